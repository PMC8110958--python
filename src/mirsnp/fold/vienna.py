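"""External MFE backend: ViennaRNA (RNAfold) Python bindings.

This is the backend the study's printed energies correspond to; it is
optional at import time so the self-contained engines keep working in
environments without the bindings.
"""

from __future__ import annotations


def available() -> bool:
    try:
        import RNA  # noqa: F401
    except ImportError:
        return False
    return True


def fold(seq: str) -> tuple[float, str]:
    """Return (MFE kcal/mol, dot-bracket structure) from RNAfold."""
    try:
        import RNA
    except ImportError as exc:  # pragma: no cover - depends on environment
        raise RuntimeError(
            "the 'external' fold engine requires the ViennaRNA Python bindings "
            "(module 'RNA'); use engine='loop_energy' for the built-in model"
        ) from exc
    structure, mfe = RNA.fold(seq)
    return float(mfe), structure
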
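"""Versioned physical-constants table.

The constants (enzyme subunit masses, extinction coefficients, compound molar
masses) ship as a plain key-value text file under ``psicascade/data`` and are
parsed once at import.  Values marked ``suspect`` in the file are kept as
printed but listed in :data:`SUSPECT_KEYS` so callers can warn on use.
"""

from __future__ import annotations

from importlib import resources

__all__ = ["CONSTANTS", "SUSPECT_KEYS", "get_constant"]


def _parse(text: str) -> tuple[dict[str, float], frozenset[str]]:
    values: dict[str, float] = {}
    suspect: set[str] = set()
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        key, _, rhs = line.partition("=")
        key = key.strip()
        fields = rhs.split()
        values[key] = float(fields[0])
        if "suspect" in fields[1:]:
            suspect.add(key)
    return values, frozenset(suspect)


CONSTANTS, SUSPECT_KEYS = _parse(
    resources.files("psicascade").joinpath("data/constants.txt").read_text()
)


def get_constant(key: str) -> float:
    """Look up a constant by key; raises ``KeyError`` with the known keys listed."""
    try:
        return CONSTANTS[key]
    except KeyError:
        raise KeyError(
            f"unknown constant {key!r}; available: {sorted(CONSTANTS)}"
        ) from None
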
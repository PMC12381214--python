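"""Small shared helpers: summary arithmetic used in reports and examples."""

from __future__ import annotations

__all__ = ["percent_change", "fold_change", "helix_contour_increment"]

#: Contour length gained per unfolded amino acid, nm (polypeptide backbone).
CONTOUR_PER_RESIDUE_NM = 0.365


def percent_change(before: float, after: float) -> float:
    """Signed percent change from ``before`` to ``after``."""
    if before == 0:
        raise ValueError("undefined percent change from zero")
    return 100.0 * (after - before) / before


def fold_change(before: float, after: float) -> float:
    """Ratio after/before."""
    if before == 0:
        raise ValueError("undefined fold change from zero")
    return after / before


def helix_contour_increment(
    n_residues: int, rise_per_residue: float = CONTOUR_PER_RESIDUE_NM
) -> float:
    """Contour-length increment (nm) released by unfolding ``n_residues``."""
    if n_residues < 0:
        raise ValueError("n_residues must be non-negative")
    return n_residues * rise_per_residue
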
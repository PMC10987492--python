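"""Stall-site prediction and spacer (distance_LS) statistics.

Stall sites follow two experimentally established rules: for elongation
arrest on a four-residue RAPP-like motif the ribosome stalls with the codon
of the motif's *third* residue in the P-site; for termination arrest the
stop codon occupies the A-site, i.e. the P-site holds the protein's final
residue.  Families whose stall site lies downstream of the conserved motif
(KYxIW-like) use a per-family offset override instead.

distance_LS is the number of residues between the last residue of the
N-terminal localization signal and the P-site residue of the arrest site.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gaussian_kde

from arrestscreen.localization import LocalizationSignal
from arrestscreen.motifs import MotifHit


# stall-site overrides for families where the tetrad rule does not apply:
# code -> offset of the P-site downstream of the motif's last residue.
# KYxIW: strongest toeprint signal six residues past the tryptophan.
DEFAULT_STALL_OVERRIDES: dict[str, int] = {"KYxIW": 6}


@dataclass(frozen=True)
class ArrestSite:
    """Predicted stalled-ribosome geometry (1-based residue indices).

    For termination-mode arrest the A-site index is protein length + 1,
    denoting the stop codon.
    """

    mode: str
    p_site: int
    a_site: int
    motif_ref: MotifHit | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("elongation", "termination"):
            raise ValueError(f"bad arrest mode {self.mode!r}")
        if self.a_site != self.p_site + 1:
            raise ValueError("A-site must immediately follow the P-site")


@dataclass
class SpacerStats:
    """Summary of a distance_LS cohort, optionally split into modes."""

    values: list[int]
    median: float
    groups: list[tuple[float, int]] = field(default_factory=list)
    n: int = 0
    split_point: float | None = None


def predict_arrest_site(
    protein: str,
    hit: MotifHit,
    overrides: dict[str, int] | None = None,
) -> ArrestSite:
    """Predict the stall site implied by a classified motif hit.

    Elongation hits must be four-residue motifs (the third-residue rule is
    defined for tetrads); termination hits put the stop codon in the A-site
    regardless of motif length; override-class hits take the P-site at a
    per-family offset downstream of the motif.
    """
    if hit.query is None:
        raise ValueError("hit must carry its query to determine the arrest mode")
    overrides = DEFAULT_STALL_OVERRIDES if overrides is None else overrides
    klass = hit.query.klass
    length = len(protein)
    if klass == "termination":
        return ArrestSite(mode="termination", p_site=length, a_site=length + 1, motif_ref=hit)
    if klass == "override":
        offset = overrides.get(hit.query.code)
        if offset is None:
            raise ValueError(f"no stall-site override registered for {hit.query.code!r}")
        p_site = hit.match_end + offset
        if p_site > length:
            raise ValueError(
                f"override stall site {p_site} beyond protein length {length}"
            )
        return ArrestSite(mode="elongation", p_site=p_site, a_site=p_site + 1, motif_ref=hit)
    if len(hit.pattern) != 4:
        raise ValueError(
            f"third-residue rule is defined for tetrads; got pattern {hit.pattern!r}"
        )
    p_site = hit.match_start + 2
    return ArrestSite(mode="elongation", p_site=p_site, a_site=p_site + 1, motif_ref=hit)


def relative_cterm_position(protein_length: int, residue_index: int) -> int:
    """Residue position counted from the C-terminal end (final residue = -1)."""
    if not (1 <= residue_index <= protein_length):
        raise ValueError(
            f"residue_index {residue_index} out of range 1..{protein_length}"
        )
    return residue_index - protein_length - 1


def ptc_separation(p_site: int, residue_index: int) -> int:
    """Residues separating a nascent-chain residue from the PTC.

    Measured as the A-site index minus the residue index; the P-site
    residue itself is 1 residue from the PTC.
    """
    if residue_index > p_site:
        raise ValueError(
            f"residue {residue_index} lies beyond the P-site {p_site}"
        )
    return (p_site + 1) - residue_index


def distance_ls(arrest_site: ArrestSite, signal: LocalizationSignal) -> int:
    """distance_LS: P-site residue minus the localization-signal end."""
    if signal.signal_end >= arrest_site.p_site:
        raise ValueError(
            f"signal end {signal.signal_end} at or beyond the P-site "
            f"{arrest_site.p_site}: inconsistent annotation"
        )
    return arrest_site.p_site - signal.signal_end


def _kde_split_point(values: np.ndarray) -> float | None:
    """Valley of a bimodal Gaussian KDE (Silverman bandwidth), or None.

    A split is reported only when the density has exactly two interior
    local maxima separated by exactly one interior local minimum.
    """
    if np.ptp(values) == 0:
        return None
    kde = gaussian_kde(values.astype(float), bw_method="silverman")
    lo, hi = values.min(), values.max()
    pad = 0.05 * (hi - lo)
    grid = np.linspace(lo - pad, hi + pad, 512)
    dens = kde(grid)
    d = np.diff(dens)
    maxima = [i + 1 for i in range(len(d) - 1) if d[i] > 0 >= d[i + 1]]
    minima = [i + 1 for i in range(len(d) - 1) if d[i] < 0 <= d[i + 1]]
    interior_min = [i for i in minima if maxima and maxima[0] < i < maxima[-1]]
    if len(maxima) == 2 and len(interior_min) == 1:
        return float(grid[interior_min[0]])
    return None


def spacer_distribution(
    values: list[int] | np.ndarray, split: str | float = "auto"
) -> SpacerStats:
    """Summarize a distance_LS cohort, splitting bimodal distributions.

    ``split='auto'`` detects a valley by Gaussian-kernel density
    (Silverman bandwidth) and, when the density is cleanly bimodal, splits
    there; ``split='none'`` never splits; a numeric ``split`` forces the
    given threshold.  Group medians are reported in ascending order.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("spacer_distribution requires at least one value")
    overall = float(np.median(arr))

    split_point: float | None
    if split == "none":
        split_point = None
    elif split == "auto":
        split_point = _kde_split_point(arr)
    else:
        split_point = float(split)

    if split_point is None:
        groups = [(overall, int(arr.size))]
    else:
        lower = arr[arr <= split_point]
        upper = arr[arr > split_point]
        if lower.size == 0 or upper.size == 0:
            groups = [(overall, int(arr.size))]
            split_point = None
        else:
            groups = [
                (float(np.median(lower)), int(lower.size)),
                (float(np.median(upper)), int(upper.size)),
            ]
    return SpacerStats(
        values=[int(v) if float(v).is_integer() else float(v) for v in arr],
        median=overall,
        groups=sorted(groups),
        n=int(arr.size),
        split_point=split_point,
    )
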
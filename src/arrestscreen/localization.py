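"""N-terminal localization-signal prediction from hydropathy.

A built-in sliding-window Kyte–Doolittle heuristic locates an N-terminal
hydrophobic segment and classifies it as a cleavable signal peptide (when an
A-x-A-like small-residue motif follows) or a transmembrane (TM) segment.
Pre-computed predictions from external tools can be supplied instead through
:func:`read_predictions_tsv`; downstream logic only needs the segment
intervals and the signal-end residue.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

# Kyte & Doolittle residue hydropathy
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
    "X": 0.0,
}

_SCALES = {"kyte_doolittle": KYTE_DOOLITTLE}

# residues treated as "small" at signal-peptidase-like cleavage sites
SMALL_RESIDUES = frozenset("AGS")


@dataclass
class HydropathyParams:
    """Knobs of the hydropathy heuristic.

    ``window`` must be odd; ``tm_threshold`` is the mean windowed hydropathy
    above which a center residue counts as hydrophobic; a candidate segment
    must be at least ``min_segment_len`` residues long and start at or
    before residue ``n_region_max_start``.
    """

    scale: str = "kyte_doolittle"
    window: int = 19
    tm_threshold: float = 1.6
    min_segment_len: int = 15
    n_region_max_start: int = 35

    def __post_init__(self) -> None:
        if self.window % 2 == 0 or self.window < 1:
            raise ValueError("window must be a positive odd integer")
        if self.scale not in _SCALES:
            raise ValueError(f"unknown hydropathy scale {self.scale!r}")
        if not (np.isfinite(self.tm_threshold) and np.isfinite(self.n_region_max_start)):
            raise ValueError("thresholds must be finite")

    @property
    def scale_values(self) -> dict[str, float]:
        return _SCALES[self.scale]


@dataclass
class LocalizationSignal:
    """Predicted N-terminal localization signal.

    ``segments`` are 1-based inclusive residue intervals of hydrophobic
    stretches; ``signal_end`` is the last residue of the signal — the
    residue preceding the cleavage site for a signal peptide, or the last
    residue of the first TM segment.
    """

    kind: str  # "signal_peptide" | "TM"
    segments: list[tuple[int, int]] = field(default_factory=list)
    signal_end: int = 0
    topology: str = "unknown"

    def __post_init__(self) -> None:
        if self.kind not in ("signal_peptide", "TM"):
            raise ValueError(f"kind must be signal_peptide or TM, got {self.kind!r}")
        prev_end = 0
        for start, end in self.segments:
            if start <= prev_end or end < start:
                raise ValueError("segments must be sorted and non-overlapping")
            prev_end = end
        if self.segments and self.signal_end < self.segments[0][0]:
            raise ValueError("signal_end must not precede the first segment")


def hydropathy_profile(protein: str, params: HydropathyParams | None = None) -> np.ndarray:
    """Windowed mean hydropathy, one value per center residue.

    The value at index i corresponds to residue ``i + window//2 + 1``
    (1-based); termini without a full window are omitted.
    """
    params = params or HydropathyParams()
    w = params.window
    if len(protein) < w:
        raise ValueError(
            f"protein length {len(protein)} < window {w}; use a smaller window"
        )
    scale = params.scale_values
    values = np.array([scale.get(res, 0.0) for res in protein.upper()])
    kernel = np.ones(w) / w
    return np.convolve(values, kernel, mode="valid")


def profile_centers(protein: str, params: HydropathyParams | None = None) -> np.ndarray:
    """1-based residue positions corresponding to hydropathy_profile values."""
    params = params or HydropathyParams()
    half = params.window // 2
    return np.arange(half + 1, len(protein) - half + 1)


def _hydrophobic_runs(above: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start_idx, end_idx) inclusive, 0-based."""
    runs = []
    start = None
    for i, flag in enumerate(above):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(above) - 1))
    return runs


def _cleavage_motif(protein: str, seg_end: int, lookahead: int = 8) -> int | None:
    """Find an A-x-A-like motif within ``lookahead`` residues after a segment.

    Returns the 1-based cleavage position (first residue of the mature
    protein) or None.  The motif requires small residues at positions p and
    p+2; cleavage follows p+2.
    """
    upper = protein.upper()
    # motif occupies p..p+2 and must end within `lookahead` residues of the segment
    for p in range(seg_end + 1, min(seg_end + lookahead - 2, len(upper) - 2) + 1):
        if upper[p - 1] in SMALL_RESIDUES and upper[p + 1] in SMALL_RESIDUES:
            return p + 3
    return None


def predict_localization_signal(
    protein: str, params: HydropathyParams | None = None
) -> LocalizationSignal | None:
    """Predict the N-terminal localization signal of a protein, if any.

    A window-mean hydropathy run above ``tm_threshold`` seeds a segment,
    which is extended outward over per-residue-hydrophobic (KD > 0)
    neighbors.  The first segment must start at or before
    ``n_region_max_start`` and span at least ``min_segment_len`` residues.
    A small-residue A-x-A-like motif within 8 residues after the first
    segment marks a cleavable signal peptide; otherwise the signal is a TM
    segment.  The built-in heuristic does not infer topology.
    """
    params = params or HydropathyParams()
    if len(protein) < max(30, params.window):
        return None
    profile = hydropathy_profile(protein, params)
    centers = profile_centers(protein, params)
    scale = params.scale_values
    upper = protein.upper()

    segments: list[tuple[int, int]] = []
    for run_start, run_end in _hydrophobic_runs(profile > params.tm_threshold):
        start = int(centers[run_start])
        end = int(centers[run_end])
        # extend over residues that are themselves hydrophobic
        while start > 1 and scale.get(upper[start - 2], 0.0) > 0:
            start -= 1
        while end < len(upper) and scale.get(upper[end], 0.0) > 0:
            end += 1
        if segments and start <= segments[-1][1]:
            # merge with previous extended segment
            segments[-1] = (segments[-1][0], max(end, segments[-1][1]))
            continue
        if end - start + 1 >= params.min_segment_len:
            segments.append((start, end))

    if not segments or segments[0][0] > params.n_region_max_start:
        return None

    first_start, first_end = segments[0]
    cleavage = _cleavage_motif(protein, first_end)
    if cleavage is not None:
        return LocalizationSignal(
            kind="signal_peptide",
            segments=[segments[0]],
            signal_end=cleavage - 1,
        )
    return LocalizationSignal(kind="TM", segments=segments, signal_end=first_end)


def has_min_soluble_tail(
    conserved_end: int, signal: LocalizationSignal, min_spacer: int = 30
) -> bool:
    """Is the soluble domain after the localization signal long enough?

    ``conserved_end`` is the C-terminal end of the conserved region (the
    protein length serves as a proxy when no motif is known yet).  True iff
    ``conserved_end - signal_end > min_spacer``.
    """
    return (conserved_end - signal.signal_end) > min_spacer


def read_predictions_tsv(path: str | Path) -> dict[str, LocalizationSignal]:
    """Adapter: load external localization predictions.

    Expected columns: protein_id, kind, seg_start, seg_end, cleavage_pos
    (empty/NaN cleavage_pos for TM predictions).  Several rows with the
    same protein_id contribute multiple TM segments; topology may be given
    in an optional ``topology`` column.
    """
    df = pd.read_csv(path, sep="\t")
    out: dict[str, LocalizationSignal] = {}
    for protein_id, group in df.groupby("protein_id", sort=False):
        group = group.sort_values("seg_start")
        segments = [(int(r.seg_start), int(r.seg_end)) for r in group.itertuples()]
        first = group.iloc[0]
        kind = str(first["kind"])
        topology = str(first["topology"]) if "topology" in group.columns else "unknown"
        if kind == "signal_peptide" and pd.notna(first.get("cleavage_pos")):
            signal_end = int(first["cleavage_pos"]) - 1
        else:
            signal_end = segments[0][1]
        out[str(protein_id)] = LocalizationSignal(
            kind=kind, segments=segments, signal_end=signal_end, topology=topology
        )
    return out
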
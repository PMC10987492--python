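"""C-terminal arrest-motif scanning, charge filtering and family assignment.

The query panel covers RAPP-like tetrads of experimentally demonstrated
arrest peptides (RAGP of SecM, RAPP of ApdA/ApdP, RAPG of ApcA, RGSP) plus
tetrads recovered from uORFs clustering with them, the LPPP/xPPP panel, the
terminal-proline motifs (NSP-stop, NAP-stop), the DGMK-stop motif and the
KYxIW motif.  'x' in a pattern matches any residue; a terminal-anchored
pattern matches only at the protein's last residue (the '*' = stop
convention).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import yaml

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# charge model for the sliding-window filter: full integer charges only
DEFAULT_CHARGE_SCALE = {"D": -1, "E": -1, "K": 1, "R": 1}


@dataclass(frozen=True)
class MotifQuery:
    """A query motif over the 20 amino acids plus the 'x' wildcard.

    ``anchor`` is ``internal_cterm_window`` (match within the last
    ``window`` residues) or ``terminal`` (match flush with the C-terminus).
    ``klass`` tags the expected arrest mode: ``elongation`` (tetrad rule)
    or ``termination`` (stop codon in the A-site).  ``code`` is the family
    motif code used in family names (e.g. RQH, LPPP, NSP-stop).
    """

    pattern: str
    anchor: str = "internal_cterm_window"
    klass: str = "elongation"
    code: str = ""
    window: int | None = None

    def __post_init__(self) -> None:
        if len(self.pattern) < 3:
            raise ValueError(f"pattern {self.pattern!r} shorter than 3 residues")
        if self.anchor not in ("internal_cterm_window", "terminal"):
            raise ValueError(f"bad anchor {self.anchor!r}")
        if self.klass not in ("elongation", "termination", "override"):
            raise ValueError(f"bad class {self.klass!r}")
        if set(self.pattern) - set(AMINO_ACIDS) - {"x"}:
            raise ValueError(
                f"pattern {self.pattern!r} may contain only amino acids and 'x'"
            )

    def regex(self) -> re.Pattern:
        return re.compile("".join("." if c == "x" else re.escape(c) for c in self.pattern))


@dataclass(frozen=True)
class MotifHit:
    """A single motif match; coordinates are 1-based inclusive residues."""

    protein_id: str
    pattern: str
    match_start: int
    match_end: int
    matched: str
    query: MotifQuery | None = None

    def __post_init__(self) -> None:
        if self.match_end - self.match_start + 1 != len(self.pattern):
            raise ValueError("hit span inconsistent with pattern length")


@dataclass
class FamilyAssignment:
    """An order-level homology family (or orphan) of motif-bearing uORFs.

    A conserved query motif shared by more than two uORFs from species of
    the same bacterial order defines a family named
    ``{uA|uDF|uC}_{motif_code}_{order}``; one or two sharers are orphans.
    """

    family_name: str
    downstream_code: str
    motif_code: str
    order: str
    members: list = field(default_factory=list)
    orphan: bool = False


@dataclass
class ChargeFilterParams:
    """Sliding-window net-charge filter used for MifM-like candidates."""

    window: int = 5
    threshold: float = -0.3
    region: tuple[int, int] = (70, 100)
    charge_scale: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_CHARGE_SCALE))

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1")


# ---------------------------------------------------------------------------
# Query panels

# RAPP-like tetrads: known arrest motifs, SecM-cluster variants,
# ApcA-cluster variants, RAPP-cluster variants and order-conserved
# XAPP/XGPP/RxGP motifs.  All carry family code RQH.
_RQH_TETRADS = [
    # demonstrated arrest motifs
    "RAGP", "RAPP", "RAPG", "RGSP",
    # found clustered with SecM
    "LAGP", "RADP", "RASP",
    # found clustered with ApcA
    "RAPS", "RAPA", "RAPT", "RGPT", "RAPQ", "RAPE", "RGPS", "RGPG",
    "RAPC", "RAPD", "RAPV",
    # found clustered with RAPP-bearing uORFs
    "RGPP", "HGPP", "RSPP",
    # order-conserved di-proline/RxGP motifs
    "QAPP", "HAPP", "TGPP", "RDGP",
]


def default_query_panel(rap_star_terminal: bool = True) -> list[MotifQuery]:
    """The full query-motif panel.

    ``rap_star_terminal`` controls the reading of the RAP* query: True
    (default) treats '*' as the stop codon, i.e. a terminal-anchored R-A-P;
    False reads it as R-A-P-x anywhere in the C-terminal window.
    """
    panel = [
        MotifQuery(pattern=t, anchor="internal_cterm_window", klass="elongation", code="RQH")
        for t in _RQH_TETRADS
    ]
    if rap_star_terminal:
        panel.append(
            MotifQuery(pattern="RAP", anchor="terminal", klass="termination", code="RQH")
        )
    else:
        panel.append(
            MotifQuery(pattern="RAPx", anchor="internal_cterm_window",
                       klass="elongation", code="RQH")
        )
    panel.extend(
        [
            # LPPP family: motif within the last 15 residues
            MotifQuery(pattern="LPPP", anchor="internal_cterm_window",
                       klass="elongation", code="LPPP", window=15),
            # terminal-proline families (stop codon in the A-site)
            MotifQuery(pattern="NSP", anchor="terminal", klass="termination",
                       code="NSP-stop"),
            MotifQuery(pattern="NAP", anchor="terminal", klass="termination",
                       code="NAP-stop"),
            MotifQuery(pattern="DGMK", anchor="terminal", klass="termination",
                       code="DGMK-stop"),
            # KYxIW: stall site downstream of the motif (per-family override)
            MotifQuery(pattern="KYxIW", anchor="internal_cterm_window",
                       klass="override", code="KYxIW"),
        ]
    )
    return panel


# whole-proteome scan panel of RAPP-like tetrads
PROTEOME_SCAN_PANEL = (
    "RAPP", "RGPP", "HAPP", "HGPP", "QAPP", "QGPP", "RAGP", "RAPG", "RPPP",
)


def load_query_panel(path: str | Path) -> list[MotifQuery]:
    """Load a query panel from YAML/JSON: a list of mappings with keys
    pattern / anchor / class / code / window."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    panel = []
    for entry in data:
        panel.append(
            MotifQuery(
                pattern=entry["pattern"],
                anchor=entry.get("anchor", "internal_cterm_window"),
                klass=entry.get("class", entry.get("klass", "elongation")),
                code=entry.get("code", ""),
                window=entry.get("window"),
            )
        )
    return panel


# ---------------------------------------------------------------------------
# Scanning

def scan_cterm_motifs(
    protein: str,
    queries: list[MotifQuery],
    window_len: int = 30,
    protein_id: str = "",
) -> list[MotifHit]:
    """All matches of the query panel near the protein's C-terminus.

    Internal queries report every (possibly overlapping) match whose end
    lies within the last ``window_len`` residues (or the query's own
    window override); terminal queries match only flush with the last
    residue.  Hits are sorted by match_end then match_start.
    """
    length = len(protein)
    hits: list[MotifHit] = []
    for query in queries:
        regex = query.regex()
        if query.anchor == "terminal":
            start = length - len(query.pattern)
            if start >= 0 and regex.fullmatch(protein, start):
                hits.append(
                    MotifHit(
                        protein_id=protein_id,
                        pattern=query.pattern,
                        match_start=start + 1,
                        match_end=length,
                        matched=protein[start:],
                        query=query,
                    )
                )
            continue
        window = query.window if query.window is not None else window_len
        pos = 0
        while True:
            m = regex.search(protein, pos)
            if m is None:
                break
            end = m.start() + len(query.pattern)  # 1-based inclusive end
            if end > length - window:
                hits.append(
                    MotifHit(
                        protein_id=protein_id,
                        pattern=query.pattern,
                        match_start=m.start() + 1,
                        match_end=end,
                        matched=protein[m.start() : end],
                        query=query,
                    )
                )
            pos = m.start() + 1  # allow overlapping matches
    hits.sort(key=lambda h: (h.match_end, h.match_start, h.pattern))
    return hits


def most_cterminal_diproline(protein: str, protein_id: str = "") -> MotifHit | None:
    """The rightmost P-P occurrence, or None.

    When several di-proline motifs occur, only the most C-terminal one is
    considered (overlapping pairs inside a proline run count from their
    rightmost start).
    """
    idx = protein.rfind("PP")
    if idx < 0:
        return None
    return MotifHit(
        protein_id=protein_id,
        pattern="PP",
        match_start=idx + 1,
        match_end=idx + 2,
        matched="PP",
    )


def local_charge_profile(
    protein: str, params: ChargeFilterParams | None = None
) -> list[tuple[int, float]]:
    """Sliding-window mean net charge per residue.

    Returns (center_position, mean_charge) for every full window; an empty
    list if the protein is shorter than the window.
    """
    params = params or ChargeFilterParams()
    w = params.window
    if len(protein) < w:
        return []
    scale = params.charge_scale
    charges = [scale.get(res, 0) for res in protein.upper()]
    half = w // 2
    out = []
    for i in range(len(protein) - w + 1):
        center = i + half + 1  # 1-based
        out.append((center, sum(charges[i : i + w]) / w))
    return out


def mifm_charge_filter(protein: str, params: ChargeFilterParams | None = None) -> bool:
    """Does the protein carry a MifM-like acidic patch?

    True iff the minimum windowed mean charge, over windows whose center
    lies in the configured region (70–100 by default, clipped to the
    sequence), is below the threshold (−0.3).  Proteins too short to place
    any window center in the region fail the filter.
    """
    params = params or ChargeFilterParams()
    profile = local_charge_profile(protein, params)
    lo, hi = params.region
    in_region = [chg for center, chg in profile if lo <= center <= hi]
    if not in_region:
        return False
    return min(in_region) < params.threshold


def assign_families(
    hits: dict,
    candidates: dict,
    taxonomy: dict[str, dict[str, str]] | None = None,
) -> list[FamilyAssignment]:
    """Group motif-bearing candidates into order-level families.

    Parameters
    ----------
    hits:
        candidate_id -> MotifHit (the hit defining the candidate's motif
        code; use the most C-terminal hit when several matched).
    candidates:
        candidate_id -> UorfCandidate (supplies target_class and taxonomy).
    taxonomy:
        optional genome_id -> {phylum, order} override; when absent the
        candidate's own taxonomy is used.

    Per (target_class, motif_code, order): three or more members form a
    family named ``{target_class}_{motif_code}_{order}``; one or two
    members are reported as orphans (same name, ``orphan=True``).
    """
    groups: dict[tuple[str, str, str], list] = {}
    for cand_id, hit in hits.items():
        cand = candidates[cand_id]
        if taxonomy is not None and cand.genome_id in taxonomy:
            tax = taxonomy[cand.genome_id]
        else:
            tax = cand.taxonomy
        order = tax.get("order")
        if not order:
            raise ValueError(
                f"candidate {cand_id}: genome {cand.genome_id} has no order-level taxonomy"
            )
        code = hit.query.code if hit.query is not None else hit.pattern
        groups.setdefault((cand.target_class, code, order), []).append(cand_id)
    out = []
    for (target_class, code, order), members in sorted(groups.items()):
        out.append(
            FamilyAssignment(
                family_name=f"{target_class}_{code}_{order}",
                downstream_code=target_class,
                motif_code=code,
                order=order,
                members=sorted(members),
                orphan=len(members) < 3,
            )
        )
    return out


def proteome_rapp_scan(
    proteome: dict[str, str], panel: tuple[str, ...] | None = None
) -> list[MotifHit]:
    """Whole-proteome scan for RAPP-like tetrads (no C-terminal window).

    ``panel`` defaults to the nine literal tetrads RAPP, RGPP, HAPP, HGPP,
    QAPP, QGPP, RAGP, RAPG and RPPP.  Every occurrence in every protein is
    reported.
    """
    panel = tuple(panel) if panel is not None else PROTEOME_SCAN_PANEL
    hits: list[MotifHit] = []
    for protein_id in sorted(proteome):
        protein = proteome[protein_id]
        for pattern in panel:
            query = MotifQuery(pattern=pattern, anchor="internal_cterm_window",
                               klass="elongation", code="RQH")
            regex = query.regex()
            pos = 0
            while True:
                m = regex.search(protein, pos)
                if m is None:
                    break
                hits.append(
                    MotifHit(
                        protein_id=protein_id,
                        pattern=pattern,
                        match_start=m.start() + 1,
                        match_end=m.start() + len(pattern),
                        matched=m.group(0),
                        query=query,
                    )
                )
                pos = m.start() + 1
    hits.sort(key=lambda h: (h.protein_id, h.match_start, h.pattern))
    return hits
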
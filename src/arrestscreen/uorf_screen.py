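"""Target-gene discovery and upstream-ORF extraction.

The screen looks for small proteins encoded immediately upstream of, and
co-oriented with, the protein-localization genes *secA*, *secDF* and *yidC*.
Target genes are found either from their product annotation or by local
alignment against user-supplied query proteins (a blastp stand-in).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace

from Bio.Align import PairwiseAligner, substitution_matrices

from arrestscreen.genome_io import GeneFeature, GenomeRecord, feature_protein

# Downstream-gene class tags: uA = uORF of secA, uDF = secDF, uC = yidC.
TARGET_CLASSES = ("uA", "uDF", "uC")

# product-annotation keywords marking each target class (SecD and SecF both
# map to uDF since secDF may be a fusion or a two-gene pair)
_TARGET_ANNOTATION = {
    "seca": "uA",
    "secd": "uDF",
    "secf": "uDF",
    "secdf": "uDF",
    "yidc": "uC",
}

DEFAULT_UNKNOWN_FUNCTION_KEYWORDS = [
    "hypothetical",
    "putative",
    "uncharacterized",
    "unknown",
    "duf",
    "membrane protein",
    "extracytoplasmic protein",
]

DEFAULT_KNOWN_SUBSTRATE_KEYWORDS = [
    "secm",
    "mifm",
    "vemp",
    "monitor",
    "translation regulator",
    "regulator of oxaab translation",
]


@dataclass
class ScreenCriteria:
    """Tunable thresholds of the uORF screen.

    ``max_uorf_len`` is exclusive (a 300-residue protein is rejected);
    ``min_spacer`` is the minimum soluble tail after the localization signal.
    """

    max_uorf_len: int = 300
    min_spacer: int = 30
    unknown_function_keywords: list[str] = field(
        default_factory=lambda: list(DEFAULT_UNKNOWN_FUNCTION_KEYWORDS)
    )
    known_substrate_keywords: list[str] = field(
        default_factory=lambda: list(DEFAULT_KNOWN_SUBSTRATE_KEYWORDS)
    )
    max_intergenic_gap: int = 1000
    target_queries: dict[str, list[str]] = field(default_factory=dict)
    similarity_min_identity: float = 0.30
    similarity_min_coverage: float = 0.50

    def __post_init__(self) -> None:
        if self.max_uorf_len <= 0:
            raise ValueError("max_uorf_len must be positive")
        if self.min_spacer < 0:
            raise ValueError("min_spacer must be >= 0")
        self.unknown_function_keywords = [k.lower() for k in self.unknown_function_keywords]
        self.known_substrate_keywords = [k.lower() for k in self.known_substrate_keywords]


@dataclass
class UorfCandidate:
    """A small upstream ORF co-oriented with its downstream target gene."""

    genome_id: str
    taxonomy: dict[str, str]
    uorf_feature: GeneFeature
    protein: str
    target_class: str
    target_locus_tag: str
    intergenic_gap: int
    annotation_category: str | None = None

    def to_row(self) -> dict:
        return {
            "genome_id": self.genome_id,
            "phylum": self.taxonomy.get("phylum", ""),
            "order": self.taxonomy.get("order", ""),
            "contig_id": self.uorf_feature.contig_id,
            "locus_tag": self.uorf_feature.locus_tag,
            "start": self.uorf_feature.start,
            "end": self.uorf_feature.end,
            "strand": self.uorf_feature.strand,
            "product": self.uorf_feature.product,
            "protein": self.protein,
            "target_class": self.target_class,
            "target_locus_tag": self.target_locus_tag,
            "intergenic_gap": self.intergenic_gap,
            "annotation_category": self.annotation_category or "",
        }


# ---------------------------------------------------------------------------
# Local-alignment homolog detection (blastp stand-in)

def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def sw_hit(
    protein: str,
    query: str,
    min_identity: float = 0.30,
    min_coverage: float = 0.50,
) -> bool:
    """Smith–Waterman (BLOSUM62, gap 11/1) homology test.

    Accepts iff fractional identity over the aligned columns is at least
    ``min_identity`` and the alignment covers at least ``min_coverage`` of
    the query length.
    """
    if not protein or not query:
        return False
    aligner = _make_aligner()
    try:
        aln = aligner.align(query, protein)[0]
    except (IndexError, ValueError):
        return False
    counts = aln.counts()
    aligned_cols = counts.identities + counts.mismatches + counts.gaps
    if aligned_cols == 0:
        return False
    identity = counts.identities / aligned_cols
    q_aligned = sum(e - s for s, e in aln.aligned[0])
    coverage = q_aligned / len(query)
    return identity >= min_identity and coverage >= min_coverage


def shuffled(protein: str, seed: int = 0) -> str:
    """Residue-shuffled version of a protein (composition-preserving null)."""
    rng = random.Random(seed)
    residues = list(protein)
    rng.shuffle(residues)
    return "".join(residues)


def classify_target_by_annotation(product: str) -> str | None:
    """Map a product annotation to a target class, or None."""
    low = product.lower()
    for keyword, klass in _TARGET_ANNOTATION.items():
        if keyword in low:
            return klass
    return None


def find_target_genes(
    record: GenomeRecord,
    criteria: ScreenCriteria,
    mode: str = "annotation",
) -> list[tuple[GeneFeature, str]]:
    """Locate secA/secDF/yidC genes in a genome.

    ``mode='annotation'`` matches product strings (secA/secD/secF/yidC,
    case-insensitive).  ``mode='similarity'`` runs the local-alignment
    stand-in against ``criteria.target_queries`` (class -> query proteins).
    Each feature is tagged with exactly one class (best alignment score
    wins in similarity mode).
    """
    if mode not in ("annotation", "similarity"):
        raise ValueError(f"unknown mode {mode!r}")
    hits: list[tuple[GeneFeature, str]] = []
    if mode == "annotation":
        for feat in record.sorted_features():
            klass = classify_target_by_annotation(feat.product)
            if klass is not None:
                hits.append((feat, klass))
        return hits

    if not criteria.target_queries:
        raise ValueError("similarity mode requires non-empty target_queries")
    aligner = _make_aligner()
    for feat in record.sorted_features():
        protein = feature_protein(record, feat)
        best: tuple[float, str] | None = None
        for klass, queries in criteria.target_queries.items():
            for query in queries:
                if not sw_hit(
                    protein,
                    query,
                    criteria.similarity_min_identity,
                    criteria.similarity_min_coverage,
                ):
                    continue
                score = aligner.score(query, protein)
                if best is None or score > best[0]:
                    best = (score, klass)
        if best is not None:
            hits.append((feat, best[1]))
    return hits


# ---------------------------------------------------------------------------
# Upstream ORF extraction

def _nearest_upstream(
    record: GenomeRecord, target: GeneFeature
) -> tuple[GeneFeature, int] | None:
    """The closest CDS upstream of ``target`` in its transcription direction,
    regardless of strand, together with the intergenic gap in nt (number of
    nucleotides strictly between the two features)."""
    best: GeneFeature | None = None
    for feat in record.features:
        if feat.contig_id != target.contig_id or feat.locus_tag == target.locus_tag:
            continue
        if target.strand == "+":
            if feat.end < target.start and (best is None or feat.end > best.end):
                best = feat
        else:
            if feat.start > target.end and (best is None or feat.start < best.start):
                best = feat
    if best is None:
        return None
    if target.strand == "+":
        gap = target.start - best.end - 1
    else:
        gap = best.start - target.end - 1
    return best, gap


def extract_upstream_orf(
    record: GenomeRecord,
    target_feature: GeneFeature,
    criteria: ScreenCriteria,
    target_class: str = "uA",
) -> UorfCandidate | None:
    """Extract the uORF candidate upstream of a target gene, if any.

    Only the nearest upstream CDS is considered; it qualifies iff it lies on
    the same strand as the target (operonic co-orientation), the intergenic
    gap does not exceed ``max_intergenic_gap`` nt, and its protein is
    shorter than ``max_uorf_len`` residues.  Absence is a value, not an
    error.
    """
    found = _nearest_upstream(record, target_feature)
    if found is None:
        return None
    upstream, gap = found
    if upstream.strand != target_feature.strand:
        return None
    if gap < 0 or gap > criteria.max_intergenic_gap:
        return None
    try:
        protein = feature_protein(record, upstream)
    except Exception:
        return None
    if not protein or len(protein) >= criteria.max_uorf_len:
        return None
    return UorfCandidate(
        genome_id=record.genome_id,
        taxonomy=dict(record.taxonomy),
        uorf_feature=upstream,
        protein=protein,
        target_class=target_class,
        target_locus_tag=target_feature.locus_tag,
        intergenic_gap=gap,
    )


def filter_by_annotation(
    candidate: UorfCandidate, criteria: ScreenCriteria
) -> UorfCandidate | None:
    """Keep a candidate only if its product annotation marks it as either a
    protein of unknown function or a known monitoring substrate.

    Matching is case-insensitive substring matching on the product string.
    Known-substrate keywords take precedence when both lists match.
    """
    product = candidate.uorf_feature.product.lower()
    if any(k in product for k in criteria.known_substrate_keywords):
        return replace(candidate, annotation_category="known_substrate")
    if any(k in product for k in criteria.unknown_function_keywords):
        return replace(candidate, annotation_category="unknown_function")
    return None
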
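"""Genome I/O: FASTA + GFF3 parsing, bacterial CDS translation, result tables.

All coordinates are 1-based and inclusive on both ends, matching GFF3.
Half-open conversions, where needed, are internal and never serialized.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq


class GenomeIOError(ValueError):
    """Malformed genome bundle (missing contig, bad coordinates, ...)."""


class PseudogeneError(GenomeIOError):
    """CDS contains an internal stop codon and cannot encode a protein."""


@dataclass(frozen=True)
class GeneFeature:
    """One CDS feature on a contig.

    ``start``/``end`` are 1-based inclusive nucleotide coordinates with
    ``start <= end`` regardless of strand.
    """

    contig_id: str
    start: int
    end: int
    strand: str
    locus_tag: str
    product: str = ""
    protein_seq: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise GenomeIOError(
                f"feature {self.locus_tag}: strand must be '+' or '-', got {self.strand!r}"
            )
        if not (1 <= self.start <= self.end):
            raise GenomeIOError(
                f"feature {self.locus_tag}: bad coordinates {self.start}..{self.end}"
            )

    @property
    def length_nt(self) -> int:
        return self.end - self.start + 1


@dataclass
class GenomeRecord:
    """One annotated genome: contigs, CDS features and GTDB-style taxonomy."""

    genome_id: str
    taxonomy: dict[str, str] = field(default_factory=dict)
    contigs: dict[str, str] = field(default_factory=dict)
    features: list[GeneFeature] = field(default_factory=list)

    def validate(self) -> "GenomeRecord":
        seen: set[str] = set()
        for feat in self.features:
            if feat.contig_id not in self.contigs:
                raise GenomeIOError(
                    f"{self.genome_id}: feature {feat.locus_tag} references "
                    f"unknown contig {feat.contig_id!r}"
                )
            contig_len = len(self.contigs[feat.contig_id])
            if feat.end > contig_len:
                raise GenomeIOError(
                    f"{self.genome_id}: feature {feat.locus_tag} end {feat.end} "
                    f"exceeds contig {feat.contig_id} length {contig_len}"
                )
            if feat.locus_tag in seen:
                raise GenomeIOError(
                    f"{self.genome_id}: duplicate locus_tag {feat.locus_tag!r}"
                )
            seen.add(feat.locus_tag)
        return self

    def sorted_features(self) -> list[GeneFeature]:
        return sorted(self.features, key=lambda f: (f.contig_id, f.start, f.end))

    def reverse_complemented(self) -> "GenomeRecord":
        """Mirror image of the genome: every contig reverse-complemented,
        every feature's strand flipped and coordinates remapped.  Used for
        strand-symmetry checks."""
        new_contigs = {
            cid: str(Seq(seq).reverse_complement()) for cid, seq in self.contigs.items()
        }
        new_feats = []
        for f in self.features:
            length = len(self.contigs[f.contig_id])
            new_feats.append(
                replace(
                    f,
                    start=length - f.end + 1,
                    end=length - f.start + 1,
                    strand="-" if f.strand == "+" else "+",
                )
            )
        return GenomeRecord(
            genome_id=self.genome_id,
            taxonomy=dict(self.taxonomy),
            contigs=new_contigs,
            features=new_feats,
        ).validate()


def _feature_attribute(feat, *names: str) -> str | None:
    for name in names:
        if name in feat.attributes:
            vals = feat.attributes[name]
            if vals:
                return vals[0]
    return None


def read_genome_bundle(
    fasta_path: str | Path,
    gff_path: str | Path,
    taxonomy_row: dict[str, str] | None = None,
    genome_id: str | None = None,
) -> GenomeRecord:
    """Read a nucleotide FASTA and its GFF3 annotation into a GenomeRecord.

    Only CDS features are retained; ``gene`` lines are accepted but ignored.
    The product annotation is taken from the ``product=`` attribute, falling
    back to ``Note=``.  Features are returned sorted by (contig, start).

    Parameters
    ----------
    taxonomy_row:
        Mapping with at least ``phylum`` and ``order`` keys (GTDB-style);
        may also carry ``genome_id``.
    """
    fasta_path, gff_path = Path(fasta_path), Path(gff_path)
    taxonomy_row = dict(taxonomy_row or {})
    if genome_id is None:
        genome_id = taxonomy_row.get("genome_id", fasta_path.stem)

    contigs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    if not contigs:
        raise GenomeIOError(f"{fasta_path}: no FASTA records found")

    db = gffutils.create_db(
        str(gff_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    features: list[GeneFeature] = []
    for feat in db.features_of_type("CDS"):
        locus_tag = _feature_attribute(feat, "locus_tag", "ID")
        if locus_tag is None:
            raise GenomeIOError(f"{gff_path}: CDS at {feat.seqid}:{feat.start} lacks a locus_tag")
        product = _feature_attribute(feat, "product", "Note") or ""
        if feat.strand not in ("+", "-"):
            raise GenomeIOError(f"{gff_path}: CDS {locus_tag} has no strand")
        features.append(
            GeneFeature(
                contig_id=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand,
                locus_tag=locus_tag,
                product=product,
            )
        )

    record = GenomeRecord(
        genome_id=genome_id,
        taxonomy={k: v for k, v in taxonomy_row.items() if k != "genome_id"},
        contigs=contigs,
        features=[],
    )
    record.features = features
    record.validate()
    record.features = record.sorted_features()
    return record


def attach_proteins(record: GenomeRecord, protein_fasta: str | Path) -> GenomeRecord:
    """Fill ``protein_seq`` on features from a protein FASTA keyed by locus tag."""
    proteins = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(protein_fasta), "fasta")}
    record.features = [
        replace(f, protein_seq=proteins.get(f.locus_tag, f.protein_seq))
        for f in record.features
    ]
    return record


# NCBI translation table 11 (bacterial); alternative initiators read as Met.
_START_CODONS = {"ATG", "GTG", "TTG"}


def translate_cds(record: GenomeRecord, feature: GeneFeature) -> str:
    """Translate a CDS feature with the bacterial code (table 11).

    Alternative start codons (GTG, TTG) are translated as M.  The trailing
    stop codon is removed.  Ambiguous codons containing N translate to X.
    An internal stop codon raises :class:`PseudogeneError`.
    """
    if feature.contig_id not in record.contigs:
        raise GenomeIOError(
            f"{record.genome_id}: feature {feature.locus_tag} references "
            f"unknown contig {feature.contig_id!r}"
        )
    nt = record.contigs[feature.contig_id][feature.start - 1 : feature.end]
    if len(nt) % 3 != 0:
        raise GenomeIOError(
            f"{record.genome_id}:{feature.locus_tag}: CDS length {len(nt)} "
            "is not a multiple of 3"
        )
    seq = Seq(nt)
    if feature.strand == "-":
        seq = seq.reverse_complement()
    protein = str(seq.translate(table=11))
    if protein.endswith("*"):
        protein = protein[:-1]
    if "*" in protein:
        raise PseudogeneError(
            f"{record.genome_id}:{feature.locus_tag}: internal stop codon "
            "(pseudogene?)"
        )
    if protein and str(seq[:3]).upper() in _START_CODONS:
        protein = "M" + protein[1:]
    return protein


def feature_protein(record: GenomeRecord, feature: GeneFeature) -> str:
    """Protein sequence of a feature: annotated if present, else translated."""
    if feature.protein_seq:
        return feature.protein_seq
    return translate_cds(record, feature)


# ---------------------------------------------------------------------------
# Tables

_CANDIDATE_COLUMNS = [
    "genome_id",
    "phylum",
    "order",
    "contig_id",
    "locus_tag",
    "start",
    "end",
    "strand",
    "product",
    "protein",
    "target_class",
    "target_locus_tag",
    "intergenic_gap",
    "annotation_category",
]


def write_candidates_table(candidates, path: str | Path) -> Path:
    """Write uORF candidates to a TSV with a stable column order.

    Accepts any iterable of objects exposing ``to_row()`` (UorfCandidate)
    or plain dicts.  An empty input produces a header-only file.
    """
    path = Path(path)
    rows = []
    for cand in candidates:
        row = cand.to_row() if hasattr(cand, "to_row") else dict(cand)
        rows.append(row)
    df = pd.DataFrame(rows, columns=_CANDIDATE_COLUMNS)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_candidates_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"genome_id": str, "locus_tag": str})
    missing = set(_CANDIDATE_COLUMNS) - set(df.columns)
    if missing:
        raise GenomeIOError(f"{path}: candidate table missing columns {sorted(missing)}")
    return df


def read_taxonomy(path: str | Path) -> dict[str, dict[str, str]]:
    """Read a 3-column taxonomy TSV (genome_id, phylum, order)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    expected = {"genome_id", "phylum", "order"}
    if not expected.issubset(df.columns):
        raise GenomeIOError(f"{path}: taxonomy TSV must have columns {sorted(expected)}")
    return {
        row.genome_id: {"phylum": row.phylum, "order": row.order}
        for row in df.itertuples()
    }


def write_taxonomy(taxonomy: dict[str, dict[str, str]], path: str | Path) -> Path:
    path = Path(path)
    rows = [
        {"genome_id": gid, "phylum": tax["phylum"], "order": tax["order"]}
        for gid, tax in taxonomy.items()
    ]
    pd.DataFrame(rows, columns=["genome_id", "phylum", "order"]).to_csv(
        path, sep="\t", index=False
    )
    return path
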
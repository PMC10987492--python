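"""Synthetic annotated genomes with planted uORF–target operons.

The generator emulates the screening substrate — annotated bacterial
genomes with small arrest-peptide-like uORFs co-transcribed with
secA/secDF/yidC — at toy scale, with full ground truth recorded in a
manifest.  Every construct is designed so the built-in predictors recover
it exactly: localization signals are clean hydrophobic segments flanked by
hydrophilic residues, motif regions use residues absent from the neutral
background alphabet, and spacer lengths are drawn from a configurable
normal mixture so that bimodality analysis is testable.

What this does NOT emulate: realistic GC content or codon bias, intergenic
RNA structure, or evolutionary divergence within families — planted family
members are independent constructs sharing only the motif.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from arrestscreen.genome_io import (
    GeneFeature,
    GenomeRecord,
    translate_cds,
    write_taxonomy,
)
from arrestscreen.localization import predict_localization_signal
from arrestscreen.motifs import PROTEOME_SCAN_PANEL, default_query_panel, scan_cterm_motifs
from arrestscreen.stall_spacer import DEFAULT_STALL_OVERRIDES

# hydrophilic, charge-free residues that cannot seed any panel motif,
# cleavage motif or TM segment
NEUTRAL_ALPHABET = "TNQHY"
# strongly hydrophobic residues for TM / signal-peptide cores
HYDROPHOBIC_ALPHABET = "LIVF"

_CODONS = {
    "A": ["GCT", "GCC", "GCA", "GCG"], "C": ["TGT", "TGC"],
    "D": ["GAT", "GAC"], "E": ["GAA", "GAG"], "F": ["TTT", "TTC"],
    "G": ["GGT", "GGC", "GGA", "GGG"], "H": ["CAT", "CAC"],
    "I": ["ATT", "ATC", "ATA"], "K": ["AAA", "AAG"],
    "L": ["CTT", "CTC", "CTA", "CTG", "TTA", "TTG"], "M": ["ATG"],
    "N": ["AAT", "AAC"], "P": ["CCT", "CCC", "CCA", "CCG"],
    "Q": ["CAA", "CAG"], "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"],
    "T": ["ACT", "ACC", "ACA", "ACG"], "V": ["GTT", "GTC", "GTA", "GTG"],
    "W": ["TGG"], "Y": ["TAT", "TAC"],
}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

_TARGET_PRODUCTS = {
    "uA": "preprotein translocase subunit SecA",
    "uDF": "protein translocase subunit SecDF",
    "uC": "membrane protein insertase YidC",
}

_DECOY_PRODUCTS = [
    "DNA gyrase subunit B",
    "30S ribosomal protein S4",
    "elongation factor Tu",
    "DNA polymerase III subunit alpha",
    "citrate synthase",
]


class SyntheticSpecError(ValueError):
    """Inconsistent synthetic construct specification."""


@dataclass
class OperonSpec:
    """One planted uORF–target operon.

    ``motif`` uses the query-panel spelling: a trailing ``*`` marks a
    terminal-anchored motif (stop codon follows immediately); ``x`` is a
    wildcard filled with a neutral residue.  ``spacer`` is the planted
    distance_LS (P-site minus signal end); None draws it from the cohort's
    spacer mixture.
    """

    target_class: str = "uA"
    motif: str = "RAPP"
    code: str = "RQH"
    spacer: int | None = None
    signal_kind: str = "TM"
    intergenic_gap: int = 120
    product: str = "hypothetical protein"
    strand: str = "+"
    tail_len: int = 8
    acidic_region: tuple[int, int, int] | None = None  # (start, end, n_acidic)


@dataclass
class GenomeSpec:
    genome_id: str
    phylum: str
    order: str
    operons: list[OperonSpec] = field(default_factory=list)
    n_decoys: int = 3
    # negative controls: a target whose upstream neighbor must be rejected
    bare_target: str | None = None  # target class, or None
    bare_target_reason: str = "annotation"  # "annotation" | "strand"


@dataclass
class SyntheticConfig:
    """Study conditions of a synthetic cohort.

    ``spacer_modes`` is a list of (mean, sd, weight) components of the
    integer-rounded normal mixture from which unspecified spacers are
    drawn; the defaults mirror a short mode near 70 and a long mode near
    130 residues.
    """

    genomes: list[GenomeSpec] = field(default_factory=list)
    spacer_modes: list[tuple[float, float, float]] = field(
        default_factory=lambda: [(70.0, 5.0, 0.5), (130.0, 5.0, 0.5)]
    )
    min_spacer_draw: int = 40
    seed: int = 0

    @classmethod
    def default_cohort(cls, seed: int = 0) -> "SyntheticConfig":
        """The standard 20-genome noiseless cohort.

        Four orders carry >= 3 uORFs sharing a query motif (families), one
        order carries two (orphans), and two genomes are negative controls
        whose targets have no acceptable upstream uORF.
        """
        genomes: list[GenomeSpec] = []

        def add(n, prefix, phylum, order, **operon_kw):
            for i in range(n):
                genomes.append(
                    GenomeSpec(
                        genome_id=f"{prefix}{i + 1:02d}",
                        phylum=phylum,
                        order=order,
                        operons=[OperonSpec(strand="+" if i % 2 == 0 else "-", **operon_kw)],
                    )
                )

        add(4, "GPSE", "Proteobacteria", "Pseudomonadales",
            target_class="uA", motif="RGPP", code="RQH", signal_kind="signal_peptide")
        add(3, "GENT", "Proteobacteria", "Enterobacterales",
            target_class="uDF", motif="RGPP", code="RQH", signal_kind="signal_peptide")
        add(3, "GCLO", "Firmicutes_A", "Clostridiales",
            target_class="uC", motif="KYxIW", code="KYxIW", signal_kind="TM",
            tail_len=6)
        add(3, "GSPH", "Bacteroidota", "Sphingobacteriales",
            target_class="uA", motif="NSP*", code="NSP-stop", signal_kind="signal_peptide")
        add(3, "GPHY", "Planctomycetota", "Phycisphaerales",
            target_class="uA", motif="LPPP", code="LPPP", signal_kind="TM",
            tail_len=6)
        add(2, "GMYX", "Myxococcota", "Myxococcales",
            target_class="uA", motif="QAPP", code="RQH", signal_kind="TM")
        genomes.append(
            GenomeSpec(genome_id="GNEG01", phylum="Firmicutes", order="Bacillales",
                       bare_target="uA", bare_target_reason="annotation")
        )
        genomes.append(
            GenomeSpec(genome_id="GNEG02", phylum="Firmicutes", order="Bacillales",
                       bare_target="uDF", bare_target_reason="strand")
        )
        return cls(genomes=genomes, seed=seed)


@dataclass
class PlantedUorf:
    """Ground truth for one planted uORF (manifest entry)."""

    genome_id: str
    locus_tag: str
    protein: str
    target_class: str
    target_locus_tag: str
    intergenic_gap: int
    motif: str
    motif_code: str
    arrest_klass: str
    motif_start: int
    motif_end: int
    signal_kind: str
    segments: list[tuple[int, int]]
    signal_end: int
    spacer_ls: int
    soluble_tail: int
    p_site: int
    a_site: int
    phylum: str
    order: str
    expected_family: str = ""
    orphan: bool = False


@dataclass
class CohortManifest:
    uorfs: list[PlantedUorf] = field(default_factory=list)
    taxonomy: dict[str, dict[str, str]] = field(default_factory=dict)

    def by_locus(self) -> dict[tuple[str, str], PlantedUorf]:
        return {(u.genome_id, u.locus_tag): u for u in self.uorfs}

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "uorfs": [dataclasses.asdict(u) for u in self.uorfs],
            "taxonomy": self.taxonomy,
        }
        path.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")
        return path


# ---------------------------------------------------------------------------
# sequence construction helpers

def sample_spacer_mixture(
    modes: list[tuple[float, float, float]] | list[tuple[float, float]],
    n: int,
    rng: np.random.Generator,
    minimum: int = 40,
) -> list[int]:
    """Draw integer spacers from a normal mixture.

    ``modes`` entries are (mean, sd, weight) or (mean, sd) with equal
    weights.  Draws are rounded to integers and clipped at ``minimum``.
    """
    modes = [m if len(m) == 3 else (*m, 1.0) for m in modes]
    weights = np.array([m[2] for m in modes], dtype=float)
    weights /= weights.sum()
    out = []
    for _ in range(n):
        k = rng.choice(len(modes), p=weights)
        mean, sd, _ = modes[k]
        out.append(max(minimum, int(round(rng.normal(mean, sd)))))
    return out


def _neutral(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(NEUTRAL_ALPHABET), size=n)) if n > 0 else ""


def _hydrophobic(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(HYDROPHOBIC_ALPHABET), size=n))


def _signal_prefix(rng: np.random.Generator, kind: str) -> tuple[str, int, list[tuple[int, int]]]:
    """Build the N-terminal signal region.

    Returns (prefix, signal_end, segments); the prefix ends exactly at
    signal_end.
    """
    if kind == "TM":
        core = _hydrophobic(rng, 21)
        prefix = "M" + _neutral(rng, 3) + core
        seg = (5, 4 + len(core))
        return prefix, seg[1], [seg]
    if kind == "signal_peptide":
        core = _hydrophobic(rng, 16)
        seg = (4, 3 + len(core))
        # c-region Q-A-H-A: cleavage after the second Ala, signal end = seg end + 4
        prefix = "M" + "KK" + core + "QAHA"
        return prefix, seg[1] + 4, [seg]
    raise SyntheticSpecError(f"unknown signal kind {kind!r}")


def _build_uorf_protein(
    rng: np.random.Generator, spec: OperonSpec, spacer: int
) -> tuple[str, dict]:
    """Construct a uORF protein for an operon spec; returns (protein, info)."""
    terminal = spec.motif.endswith("*")
    motif = spec.motif[:-1] if terminal else spec.motif
    motif_literal = "".join(
        _neutral(rng, 1) if c == "x" else c for c in motif
    )
    prefix, signal_end, segments = _signal_prefix(rng, spec.signal_kind)

    if terminal:
        # stop codon in the A-site: P-site = final residue
        p_site = signal_end + spacer
        motif_end = p_site
        motif_start = motif_end - len(motif) + 1
        linker_len = motif_start - signal_end - 1
        if linker_len < 0:
            raise SyntheticSpecError(
                f"spacer {spacer} too short for terminal motif {spec.motif!r}"
            )
        protein = prefix + _neutral(rng, linker_len) + motif_literal
        klass = "termination"
    elif spec.code in DEFAULT_STALL_OVERRIDES:
        offset = DEFAULT_STALL_OVERRIDES[spec.code]
        p_site = signal_end + spacer
        motif_end = p_site - offset
        motif_start = motif_end - len(motif) + 1
        linker_len = motif_start - signal_end - 1
        if linker_len < 0:
            raise SyntheticSpecError(
                f"spacer {spacer} too short for override motif {spec.motif!r}"
            )
        protein = (
            prefix
            + _neutral(rng, linker_len)
            + motif_literal
            + _neutral(rng, offset + spec.tail_len)
        )
        klass = "override"
    else:
        if len(motif) != 4:
            raise SyntheticSpecError(
                f"elongation motif {spec.motif!r} must be a tetrad"
            )
        # third-residue rule: P-site = motif start + 2
        p_site = signal_end + spacer
        motif_start = p_site - 2
        motif_end = motif_start + 3
        linker_len = motif_start - signal_end - 1
        if linker_len < 0:
            raise SyntheticSpecError(f"spacer {spacer} too short for motif")
        protein = prefix + _neutral(rng, linker_len) + motif_literal + _neutral(
            rng, spec.tail_len
        )
        klass = "elongation"

    if spec.acidic_region is not None:
        start, end, n_acidic = spec.acidic_region
        if end > len(protein) or end > motif_start - 1:
            raise SyntheticSpecError("acidic region collides with motif or protein end")
        positions = list(range(start - 1, end))
        chosen = rng.choice(positions, size=min(n_acidic, len(positions)), replace=False)
        chars = list(protein)
        for pos in sorted(chosen):
            chars[pos] = "D" if rng.random() < 0.5 else "E"
        protein = "".join(chars)

    if len(protein) >= 300:
        raise SyntheticSpecError(f"planted uORF of {len(protein)} aa exceeds size limit")
    info = {
        "motif_literal": motif_literal,
        "motif_start": motif_start,
        "motif_end": motif_end,
        "arrest_klass": klass,
        "p_site": p_site,
        "a_site": p_site + 1,
        "signal_end": signal_end,
        "segments": segments,
        "spacer_ls": p_site - signal_end,
        "soluble_tail": len(protein) - signal_end,
    }
    return protein, info


def _encode_cds(rng: np.random.Generator, protein: str, fixed: bool = False) -> str:
    """Encode a protein as a CDS (start ATG ... stop TAA).

    Background codons are drawn uniformly over synonymous codons; ``fixed``
    uses the first codon of each set (used for motif regions so a given
    protein region always yields identical nucleotides).
    """
    codons = []
    for i, res in enumerate(protein):
        options = _CODONS[res]
        if i == 0 and res == "M":
            codons.append("ATG")
        elif fixed:
            codons.append(options[0])
        else:
            codons.append(options[int(rng.integers(len(options)))])
    return "".join(codons) + "TAA"


def _random_nt(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def _revcomp(nt: str) -> str:
    return nt.translate(_COMPLEMENT)[::-1]


def _random_protein(rng: np.random.Generator, n: int, alphabet: str = "ACDEFGHIKLMNPQRSTVWY") -> str:
    return "M" + "".join(rng.choice(list(alphabet), size=n - 1))


# ---------------------------------------------------------------------------
# genome assembly

class _ContigBuilder:
    def __init__(self, contig_id: str):
        self.contig_id = contig_id
        self.parts: list[str] = []
        self.pos = 1  # next free 1-based coordinate
        self.features: list[GeneFeature] = []

    def filler(self, rng: np.random.Generator, n: int) -> None:
        self.parts.append(_random_nt(rng, n))
        self.pos += n

    def gene(self, cds_plus: str, strand: str, locus_tag: str, product: str) -> GeneFeature:
        nt = cds_plus if strand == "+" else _revcomp(cds_plus)
        feat = GeneFeature(
            contig_id=self.contig_id,
            start=self.pos,
            end=self.pos + len(nt) - 1,
            strand=strand,
            locus_tag=locus_tag,
            product=product,
        )
        self.parts.append(nt)
        self.pos += len(nt)
        self.features.append(feat)
        return feat

    def sequence(self) -> str:
        return "".join(self.parts)


def _generate_genome(
    rng: np.random.Generator, spec: GenomeSpec, config: SyntheticConfig
) -> tuple[GenomeRecord, list[PlantedUorf]]:
    contig = _ContigBuilder(f"{spec.genome_id}_c1")
    tag_no = 0

    def next_tag() -> str:
        nonlocal tag_no
        tag_no += 5
        return f"{spec.genome_id}_{tag_no:05d}"

    def add_decoy() -> None:
        protein = _random_protein(rng, int(rng.integers(80, 350)))
        product = _DECOY_PRODUCTS[int(rng.integers(len(_DECOY_PRODUCTS)))]
        strand = "+" if rng.random() < 0.5 else "-"
        contig.gene(_encode_cds(rng, protein), strand, next_tag(), product)
        contig.filler(rng, int(rng.integers(200, 400)))

    planted: list[PlantedUorf] = []
    contig.filler(rng, 150)
    n_before = max(1, spec.n_decoys - 1)
    for _ in range(n_before):
        add_decoy()

    for operon in spec.operons:
        spacer = operon.spacer
        if spacer is None:
            spacer = sample_spacer_mixture(
                config.spacer_modes, 1, rng, config.min_spacer_draw
            )[0]
        protein, info = _build_uorf_protein(rng, operon, spacer)
        uorf_cds = _encode_cds(rng, protein)
        target_protein = _random_protein(rng, int(rng.integers(200, 280)))
        target_cds = _encode_cds(rng, target_protein)
        gap_nt = _random_nt(rng, operon.intergenic_gap)
        uorf_tag, target_tag = next_tag(), next_tag()
        if operon.strand == "+":
            uorf_feat = contig.gene(uorf_cds, "+", uorf_tag, operon.product)
            contig.parts.append(gap_nt)
            contig.pos += len(gap_nt)
            contig.gene(target_cds, "+", target_tag, _TARGET_PRODUCTS[operon.target_class])
        else:
            # transcription right-to-left: target first along the contig
            contig.gene(target_cds, "-", target_tag, _TARGET_PRODUCTS[operon.target_class])
            contig.parts.append(gap_nt)
            contig.pos += len(gap_nt)
            uorf_feat = contig.gene(uorf_cds, "-", uorf_tag, operon.product)
        contig.filler(rng, int(rng.integers(300, 500)))
        planted.append(
            PlantedUorf(
                genome_id=spec.genome_id,
                locus_tag=uorf_feat.locus_tag,
                protein=protein,
                target_class=operon.target_class,
                target_locus_tag=target_tag,
                intergenic_gap=operon.intergenic_gap,
                motif=operon.motif,
                motif_code=operon.code,
                arrest_klass=info["arrest_klass"],
                motif_start=info["motif_start"],
                motif_end=info["motif_end"],
                signal_kind=operon.signal_kind,
                segments=info["segments"],
                signal_end=info["signal_end"],
                spacer_ls=info["spacer_ls"],
                soluble_tail=info["soluble_tail"],
                p_site=info["p_site"],
                a_site=info["a_site"],
                phylum=spec.phylum,
                order=spec.order,
            )
        )

    if spec.bare_target is not None:
        # a target gene whose nearest upstream CDS must be rejected
        if spec.bare_target_reason == "annotation":
            blocker = _random_protein(rng, 120)
            contig.gene(_encode_cds(rng, blocker), "+", next_tag(), "DNA gyrase subunit B")
        else:  # opposite strand
            blocker = _random_protein(rng, 120)
            contig.gene(_encode_cds(rng, blocker), "-", next_tag(), "hypothetical protein")
        contig.parts.append(_random_nt(rng, 100))
        contig.pos += 100
        target_protein = _random_protein(rng, 220)
        contig.gene(
            _encode_cds(rng, target_protein), "+", next_tag(),
            _TARGET_PRODUCTS[spec.bare_target],
        )
        contig.filler(rng, int(rng.integers(300, 500)))

    for _ in range(max(0, spec.n_decoys - n_before)):
        add_decoy()
    contig.filler(rng, 100)

    record = GenomeRecord(
        genome_id=spec.genome_id,
        taxonomy={"phylum": spec.phylum, "order": spec.order},
        contigs={contig.contig_id: contig.sequence()},
        features=contig.features,
    ).validate()
    record.features = record.sorted_features()
    return record, planted


def _assign_expected_families(planted: list[PlantedUorf]) -> None:
    groups: dict[tuple[str, str, str], list[PlantedUorf]] = {}
    for uorf in planted:
        groups.setdefault((uorf.target_class, uorf.motif_code, uorf.order), []).append(uorf)
    for (tc, code, order), members in groups.items():
        name = f"{tc}_{code}_{order}"
        for uorf in members:
            uorf.expected_family = name
            uorf.orphan = len(members) < 3


def _verify_planted(record: GenomeRecord, planted: list[PlantedUorf]) -> None:
    """Generation-time self-consistency: the emitted genome must reproduce
    the manifest under the package's own predictors."""
    feats = {f.locus_tag: f for f in record.features}
    panel = default_query_panel()
    for uorf in planted:
        translated = translate_cds(record, feats[uorf.locus_tag])
        if translated != uorf.protein:
            raise SyntheticSpecError(
                f"{uorf.genome_id}:{uorf.locus_tag}: CDS does not re-translate "
                "to the manifest protein"
            )
        signal = predict_localization_signal(uorf.protein)
        if signal is None or signal.signal_end != uorf.signal_end:
            raise SyntheticSpecError(
                f"{uorf.genome_id}:{uorf.locus_tag}: localization prediction "
                f"does not recover the planted signal end {uorf.signal_end}"
            )
        if signal.kind != uorf.signal_kind:
            raise SyntheticSpecError(
                f"{uorf.genome_id}:{uorf.locus_tag}: predicted {signal.kind}, "
                f"planted {uorf.signal_kind}"
            )
        hits = scan_cterm_motifs(uorf.protein, panel, protein_id=uorf.locus_tag)
        if not any(
            h.match_start == uorf.motif_start and h.match_end == uorf.motif_end
            for h in hits
        ):
            raise SyntheticSpecError(
                f"{uorf.genome_id}:{uorf.locus_tag}: planted motif not recovered"
            )


def generate_cohort(
    config: SyntheticConfig, out_dir: str | Path | None = None
) -> tuple[list[GenomeRecord], CohortManifest]:
    """Generate a synthetic cohort; optionally write FASTA/GFF3/taxonomy.

    Deterministic under ``config.seed``: repeated runs produce
    byte-identical files.  The manifest is validated against the emitted
    genomes at generation time.
    """
    rng = np.random.default_rng(config.seed)
    records: list[GenomeRecord] = []
    manifest = CohortManifest()
    for spec in config.genomes:
        record, planted = _generate_genome(rng, spec, config)
        _verify_planted(record, planted)
        records.append(record)
        manifest.uorfs.extend(planted)
        manifest.taxonomy[spec.genome_id] = {"phylum": spec.phylum, "order": spec.order}
    _assign_expected_families(manifest.uorfs)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for record in records:
            write_genome_files(record, out_dir)
        write_taxonomy(manifest.taxonomy, out_dir / "taxonomy.tsv")
        manifest.to_json(out_dir / "manifest.json")
    return records, manifest


def write_genome_files(record: GenomeRecord, out_dir: str | Path) -> tuple[Path, Path]:
    """Write one genome as <genome_id>.fna + <genome_id>.gff."""
    out_dir = Path(out_dir)
    fasta_path = out_dir / f"{record.genome_id}.fna"
    gff_path = out_dir / f"{record.genome_id}.gff"
    with fasta_path.open("w") as fh:
        for contig_id, seq in record.contigs.items():
            fh.write(f">{contig_id}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    with gff_path.open("w") as fh:
        fh.write("##gff-version 3\n")
        for contig_id, seq in record.contigs.items():
            fh.write(f"##sequence-region {contig_id} 1 {len(seq)}\n")
        for feat in record.sorted_features():
            attrs = f"ID=cds-{feat.locus_tag};locus_tag={feat.locus_tag};product={feat.product}"
            fh.write(
                "\t".join(
                    [
                        feat.contig_id,
                        "synthetic",
                        "CDS",
                        str(feat.start),
                        str(feat.end),
                        ".",
                        feat.strand,
                        "0",
                        attrs,
                    ]
                )
                + "\n"
            )
    return fasta_path, gff_path


# ---------------------------------------------------------------------------
# proteome generator

def generate_proteome(
    n_proteins: int,
    planted_hits: list[tuple[str, int]],
    seed: int = 0,
    protein_len: int = 150,
    max_retries: int = 200,
) -> tuple[dict[str, str], list[dict]]:
    """Random proteome with planted RAPP-like motifs at known positions.

    ``planted_hits`` lists (motif, 1-based start position) pairs; hit *i*
    is planted into protein *i*.  Background residues are uniform over the
    20 amino acids, resampled (bounded retries) whenever a spurious panel
    motif appears, so a scan finds exactly the planted occurrences.
    """
    if len(planted_hits) > n_proteins:
        raise SyntheticSpecError("more planted hits than proteins")
    rng = np.random.default_rng(seed)
    aas = list("ACDEFGHIKLMNPQRSTVWY")

    def spurious(seq: str, allowed: tuple[int, int] | None) -> bool:
        for pattern in PROTEOME_SCAN_PANEL:
            pos = seq.find(pattern)
            while pos >= 0:
                if allowed is None or (pos + 1, pos + len(pattern)) != allowed:
                    return True
                pos = seq.find(pattern, pos + 1)
        return False

    proteome: dict[str, str] = {}
    manifest: list[dict] = []
    for i in range(n_proteins):
        planted = planted_hits[i] if i < len(planted_hits) else None
        if planted is not None:
            motif, start = planted
            if start < 1 or start + len(motif) - 1 > protein_len:
                raise SyntheticSpecError(
                    f"planted motif {motif!r} at {start} outside protein of "
                    f"{protein_len} aa"
                )
        for _ in range(max_retries):
            seq = "M" + "".join(rng.choice(aas, size=protein_len - 1))
            allowed = None
            if planted is not None:
                motif, start = planted
                seq = seq[: start - 1] + motif + seq[start - 1 + len(motif):]
                allowed = (start, start + len(motif) - 1)
            if not spurious(seq, allowed):
                break
        else:
            raise SyntheticSpecError("could not generate a clean background protein")
        pid = f"prot{i + 1:04d}"
        proteome[pid] = seq
        if planted is not None:
            motif, start = planted
            manifest.append(
                {"protein_id": pid, "motif": motif, "start": start,
                 "end": start + len(motif) - 1}
            )
    return proteome, manifest


def write_proteome_fasta(proteome: dict[str, str], path: str | Path) -> Path:
    path = Path(path)
    with path.open("w") as fh:
        for pid, seq in proteome.items():
            fh.write(f">{pid}\n{seq}\n")
    return path
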
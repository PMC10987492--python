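"""Screen orchestration: compose the per-stage operations into one pipeline.

Stage order: target discovery -> upstream ORF extraction -> annotation
filter -> localization filter -> soluble-tail filter -> dereplication ->
clustering -> motif scan / charge profile -> family assignment -> stall
sites -> spacer statistics.  Every exclusion is logged with a
machine-readable reason code so the screen is auditable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from arrestscreen.genome_io import GenomeRecord, read_genome_bundle, read_taxonomy
from arrestscreen.grouping import ClusterSet, cluster, dereplicate, similarity_matrix
from arrestscreen.localization import (
    HydropathyParams,
    has_min_soluble_tail,
    predict_localization_signal,
)
from arrestscreen.motifs import (
    ChargeFilterParams,
    FamilyAssignment,
    MotifQuery,
    assign_families,
    default_query_panel,
    mifm_charge_filter,
)
from arrestscreen.motifs import scan_cterm_motifs
from arrestscreen.stall_spacer import (
    DEFAULT_STALL_OVERRIDES,
    SpacerStats,
    distance_ls,
    predict_arrest_site,
    spacer_distribution,
)
from arrestscreen.uorf_screen import (
    ScreenCriteria,
    extract_upstream_orf,
    filter_by_annotation,
    find_target_genes,
)


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    genome_dir: str | None = None
    taxonomy_tsv: str | None = None
    out_dir: str | None = None
    target_mode: str = "annotation"
    criteria: ScreenCriteria = field(default_factory=ScreenCriteria)
    hydropathy: HydropathyParams = field(default_factory=HydropathyParams)
    charge: ChargeFilterParams = field(default_factory=ChargeFilterParams)
    cluster_mode: str = "set_cover"
    cluster_threshold: float = 0.4
    similarity_method: str = "kmer_jaccard"
    cterm_window: int = 30
    split: str | float = "auto"
    panel: list[MotifQuery] | None = None

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        payload.pop("out_dir", None)
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class ScreenReport:
    candidates: pd.DataFrame
    families: list[FamilyAssignment]
    clusters: ClusterSet
    spacer: SpacerStats | None
    counts: dict[str, int]
    exclusions: list[dict]
    config_hash: str

    def write(self, out_dir: str | Path) -> Path:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.candidates.to_csv(out_dir / "candidates.tsv", sep="\t", index=False)
        fam_rows = [
            {
                "family_name": f.family_name,
                "downstream_code": f.downstream_code,
                "motif_code": f.motif_code,
                "order": f.order,
                "n_members": len(f.members),
                "orphan": f.orphan,
                "members": ";".join(str(m) for m in f.members),
            }
            for f in self.families
        ]
        pd.DataFrame(
            fam_rows,
            columns=["family_name", "downstream_code", "motif_code", "order",
                     "n_members", "orphan", "members"],
        ).to_csv(out_dir / "families.tsv", sep="\t", index=False)
        cl_rows = [
            {"member_id": str(m), "cluster_id": i,
             "representative": str(c["representative"]), "mode": self.clusters.mode}
            for i, c in enumerate(self.clusters.clusters)
            for m in c["members"]
        ]
        pd.DataFrame(
            cl_rows, columns=["member_id", "cluster_id", "representative", "mode"]
        ).to_csv(out_dir / "clusters.tsv", sep="\t", index=False)
        spacer_payload = None
        if self.spacer is not None:
            spacer_payload = {
                "n": self.spacer.n,
                "median": self.spacer.median,
                "groups": [{"median": m, "count": c} for m, c in self.spacer.groups],
                "split_point": self.spacer.split_point,
            }
        (out_dir / "report.json").write_text(
            json.dumps(
                {
                    "config_hash": self.config_hash,
                    "counts": self.counts,
                    "spacer": spacer_payload,
                    "exclusions": self.exclusions,
                },
                indent=1,
                sort_keys=True,
            )
            + "\n"
        )
        return out_dir


def screen_records(
    records: list[GenomeRecord], config: PipelineConfig | None = None
) -> ScreenReport:
    """Run the full screen on in-memory genome records."""
    config = config or PipelineConfig()
    criteria = config.criteria
    panel = config.panel if config.panel is not None else default_query_panel()
    exclusions: list[dict] = []
    counts: dict[str, int] = {"genomes": len(records)}

    def exclude(stage: str, reason: str, genome_id: str, locus_tag: str) -> None:
        exclusions.append(
            {"stage": stage, "reason": reason, "genome_id": genome_id,
             "locus_tag": locus_tag}
        )

    # 1-2. targets and upstream ORFs
    raw_candidates = []
    n_targets = 0
    for record in records:
        try:
            targets = find_target_genes(record, criteria, mode=config.target_mode)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"find_target_genes failed on {record.genome_id}: {exc}")
        n_targets += len(targets)
        for target, klass in targets:
            cand = extract_upstream_orf(record, target, criteria, target_class=klass)
            if cand is None:
                exclude("extract", "no-uorf", record.genome_id, target.locus_tag)
                continue
            raw_candidates.append(cand)
    counts["targets"] = n_targets
    counts["upstream_orfs"] = len(raw_candidates)

    # 3. annotation filter
    annotated = []
    for cand in raw_candidates:
        kept = filter_by_annotation(cand, criteria)
        if kept is None:
            exclude("annotation", "annotation", cand.genome_id,
                    cand.uorf_feature.locus_tag)
        else:
            annotated.append(kept)
    counts["annotation_kept"] = len(annotated)

    # 4. localization filter (criterion: N-terminal signal or TM segment)
    localized = []
    for cand in annotated:
        signal = predict_localization_signal(cand.protein, config.hydropathy)
        if signal is None:
            exclude("localization", "no-signal", cand.genome_id,
                    cand.uorf_feature.locus_tag)
            continue
        localized.append((cand, signal))
    counts["signal_kept"] = len(localized)

    # 5. soluble-tail filter (conserved-region end proxied by the protein end)
    tailed = []
    for cand, signal in localized:
        if not has_min_soluble_tail(len(cand.protein), signal, criteria.min_spacer):
            exclude("soluble_tail", "spacer", cand.genome_id,
                    cand.uorf_feature.locus_tag)
            continue
        tailed.append((cand, signal))
    counts["tail_kept"] = len(tailed)

    # 6-7. dereplication and clustering of representatives
    proteins = {
        (cand.genome_id, cand.uorf_feature.locus_tag): cand.protein
        for cand, _ in tailed
    }
    representatives, rep_members = dereplicate(proteins)
    counts["representatives"] = len(representatives)
    matrix = similarity_matrix(representatives, method=config.similarity_method)
    clusters = cluster(matrix, config.cluster_threshold, config.cluster_mode) if (
        representatives
    ) else ClusterSet(mode=config.cluster_mode, clusters=[])

    # 8. motif scan, charge profile, stall sites, spacers
    cand_index = {}
    best_hits = {}
    rows = []
    ls_values = []
    membership = clusters.membership()
    rep_by_seq = {seq: membership.get(rep, rep) for rep, seq in representatives.items()}
    for cand, signal in tailed:
        cand_id = (cand.genome_id, cand.uorf_feature.locus_tag)
        cand_index[cand_id] = cand
        hits = scan_cterm_motifs(
            cand.protein, panel, window_len=config.cterm_window,
            protein_id=cand.uorf_feature.locus_tag,
        )
        charge_ok = mifm_charge_filter(cand.protein, config.charge)
        row = cand.to_row()
        row.update(
            {
                "signal_kind": signal.kind,
                "signal_end": signal.signal_end,
                "soluble_tail": len(cand.protein) - signal.signal_end,
                "mifm_charge_ok": charge_ok,
                "cluster_rep": str(rep_by_seq.get(cand.protein, "")),
                "n_motif_hits": len(hits),
            }
        )
        if hits:
            # the most C-terminal hit defines the arrest site
            hit = hits[-1]
            best_hits[cand_id] = hit
            site = predict_arrest_site(cand.protein, hit, DEFAULT_STALL_OVERRIDES)
            dls = distance_ls(site, signal)
            ls_values.append(dls)
            row.update(
                {
                    "motif_pattern": hit.pattern,
                    "motif_code": hit.query.code if hit.query else "",
                    "motif_start": hit.match_start,
                    "motif_end": hit.match_end,
                    "arrest_mode": site.mode,
                    "p_site": site.p_site,
                    "a_site": site.a_site,
                    "distance_ls": dls,
                }
            )
        else:
            exclude("motif", "no-motif", cand.genome_id, cand.uorf_feature.locus_tag)
            row.update(
                {
                    "motif_pattern": "", "motif_code": "", "motif_start": pd.NA,
                    "motif_end": pd.NA, "arrest_mode": "", "p_site": pd.NA,
                    "a_site": pd.NA, "distance_ls": pd.NA,
                }
            )
        rows.append(row)
    counts["motif_bearing"] = len(best_hits)

    # 9. families
    families = assign_families(best_hits, cand_index)
    counts["families"] = sum(1 for f in families if not f.orphan)
    counts["orphans"] = sum(len(f.members) for f in families if f.orphan)

    fam_of = {}
    for fam in families:
        for member in fam.members:
            fam_of[member] = (fam.family_name, fam.orphan)
    for row in rows:
        key = (row["genome_id"], row["locus_tag"])
        name, orphan = fam_of.get(key, ("", False))
        row["family"] = name
        row["orphan"] = orphan

    columns = [
        "genome_id", "phylum", "order", "contig_id", "locus_tag", "start", "end",
        "strand", "product", "protein", "target_class", "target_locus_tag",
        "intergenic_gap", "annotation_category", "signal_kind", "signal_end",
        "soluble_tail", "mifm_charge_ok", "cluster_rep", "n_motif_hits",
        "motif_pattern", "motif_code", "motif_start", "motif_end", "arrest_mode",
        "p_site", "a_site", "distance_ls", "family", "orphan",
    ]
    candidates_df = pd.DataFrame(rows, columns=columns)
    candidates_df = candidates_df.sort_values(["genome_id", "locus_tag"]).reset_index(
        drop=True
    )

    spacer = spacer_distribution(ls_values, split=config.split) if ls_values else None
    return ScreenReport(
        candidates=candidates_df,
        families=families,
        clusters=clusters,
        spacer=spacer,
        counts=counts,
        exclusions=exclusions,
        config_hash=config.config_hash(),
    )


def run_screen(config: PipelineConfig) -> ScreenReport:
    """Run the screen from on-disk genomes (FASTA + GFF3 + taxonomy TSV)."""
    if config.genome_dir is None:
        raise PipelineError("config.genome_dir is required")
    genome_dir = Path(config.genome_dir)
    taxonomy = read_taxonomy(config.taxonomy_tsv) if config.taxonomy_tsv else {}
    fastas = sorted(
        p for p in genome_dir.iterdir()
        if p.suffix in (".fna", ".fasta", ".fa")
    )
    records = []
    for fasta in fastas:
        gff = fasta.with_suffix(".gff")
        if not gff.exists():
            gff = fasta.with_suffix(".gff3")
        if not gff.exists():
            continue
        genome_id = fasta.stem
        tax_row = dict(taxonomy.get(genome_id, {}))
        tax_row["genome_id"] = genome_id
        records.append(read_genome_bundle(fasta, gff, tax_row))
    if not records:
        raise PipelineError(f"no genomes found in {genome_dir}")
    report = screen_records(records, config)
    if config.out_dir:
        report.write(config.out_dir)
    return report
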
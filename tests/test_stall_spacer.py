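"""Stall-site rules, PTC geometry and spacer-distribution statistics."""

import numpy as np
import pytest

from arrestscreen.localization import LocalizationSignal
from arrestscreen.motifs import MotifHit, MotifQuery, default_query_panel, scan_cterm_motifs
from arrestscreen.stall_spacer import (
    ArrestSite,
    distance_ls,
    predict_arrest_site,
    ptc_separation,
    relative_cterm_position,
    spacer_distribution,
)

from conftest import random_protein

NEUTRAL = "TNQHY"


def _protein_with_motif(rng, motif, motif_start, length):
    prefix = random_protein(rng, motif_start - 1, NEUTRAL)
    tail = random_protein(rng, length - (motif_start - 1) - len(motif), NEUTRAL)
    protein = prefix + motif + tail
    assert len(protein) == length
    return protein


def _best_hit(protein):
    hits = scan_cterm_motifs(protein, default_query_panel())
    assert hits, "expected a panel hit"
    return hits[-1]


@pytest.mark.parametrize(
    "motif,motif_start,length,expected_p_site",
    [
        ("RAGP", 163, 166, 165),  # SecM-like: arrest tetrad ends at Pro166
        ("RAGP", 88, 100, 90),    # YwcI-like
        ("LPPP", 110, 118, 112),  # LPPP family: P-site at the third Pro
        ("RGPP", 125, 131, 127),  # RGPP family member upstream of secDF
    ],
)
def test_elongation_third_residue_rule(rng, motif, motif_start, length, expected_p_site):
    protein = _protein_with_motif(rng, motif, motif_start, length)
    site = predict_arrest_site(protein, _best_hit(protein))
    assert site.mode == "elongation"
    assert site.p_site == expected_p_site
    assert site.a_site == expected_p_site + 1


def test_termination_arrest_puts_stop_in_a_site(rng):
    protein = random_protein(rng, 97, NEUTRAL) + "NSP"
    site = predict_arrest_site(protein, _best_hit(protein))
    assert site.mode == "termination"
    assert (site.p_site, site.a_site) == (100, 101)


def test_override_family_stalls_downstream_of_motif(rng):
    # KYxIW at 65-69; strongest toeprint six residues past the tryptophan
    protein = _protein_with_motif(rng, "KYLIW", 65, 80)
    site = predict_arrest_site(protein, _best_hit(protein))
    assert site.p_site == 75 and site.a_site == 76


def test_elongation_rule_requires_tetrad():
    q = MotifQuery(pattern="RAPPP", anchor="internal_cterm_window", klass="elongation", code="RQH")
    hit = MotifHit(protein_id="p", pattern="RAPPP", match_start=10, match_end=14,
                   matched="RAPPP", query=q)
    with pytest.raises(ValueError, match="tetrad"):
        predict_arrest_site("M" * 30, hit)


@pytest.mark.parametrize(
    "length,index,expected",
    [(100, 96, -5), (139, 136, -4), (60, 60, -1), (100, 98, -3)],
)
def test_relative_cterm_position(length, index, expected):
    assert relative_cterm_position(length, index) == expected


def test_relative_cterm_position_rejects_out_of_range():
    with pytest.raises(ValueError):
        relative_cterm_position(100, 101)


@pytest.mark.parametrize("p_site,index,expected", [(75, 65, 11), (75, 69, 7), (75, 75, 1)])
def test_ptc_separation(p_site, index, expected):
    assert ptc_separation(p_site, index) == expected


def test_ptc_separation_rejects_residue_past_p_site():
    with pytest.raises(ValueError):
        ptc_separation(75, 80)


def test_ptc_separation_consistent_with_relative_position():
    # counting the chain from the A-site: separation = -(relative position) - 1
    for p_site in (50, 75, 120):
        for idx in range(1, p_site + 1):
            rel = relative_cterm_position(p_site + 1, idx)  # A-site as the end
            assert ptc_separation(p_site, idx) == -rel - 1


def test_distance_ls_values_and_errors():
    signal = LocalizationSignal(kind="TM", segments=[(5, 25)], signal_end=40)
    site = ArrestSite(mode="elongation", p_site=95, a_site=96)
    assert distance_ls(site, signal) == 55
    edge = LocalizationSignal(kind="TM", segments=[(5, 25)], signal_end=94)
    assert distance_ls(site, edge) == 1
    bad = LocalizationSignal(kind="TM", segments=[(5, 25)], signal_end=95)
    with pytest.raises(ValueError, match="inconsistent"):
        distance_ls(site, bad)


def test_planted_spacers_recovered_exactly(default_cohort, default_report):
    _, manifest = default_cohort
    planted = manifest.by_locus()
    df = default_report.candidates
    for row in df.itertuples():
        truth = planted[(row.genome_id, row.locus_tag)]
        assert row.p_site == truth.p_site
        assert row.distance_ls == truth.spacer_ls


def test_third_residue_rule_holds_across_cohort(default_cohort):
    _, manifest = default_cohort
    for uorf in manifest.uorfs:
        if uorf.arrest_klass == "elongation":
            assert uorf.p_site == uorf.motif_start + 2


def test_spacer_distribution_bimodal_split(rng):
    values = list(np.round(rng.normal(70, 5, 50)).astype(int)) + list(
        np.round(rng.normal(130, 5, 50)).astype(int)
    )
    stats = spacer_distribution(values)
    assert len(stats.groups) == 2
    (m1, c1), (m2, c2) = stats.groups
    assert abs(m1 - 70) <= 3 and abs(m2 - 130) <= 3
    assert (c1, c2) == (50, 50)
    assert m1 < stats.split_point < m2
    assert c1 + c2 == stats.n


def test_spacer_distribution_constant_one_group():
    stats = spacer_distribution([54] * 20)
    assert stats.groups == [(54.0, 20)] and stats.median == 54.0


def test_spacer_distribution_unimodal_one_group(rng):
    values = list(np.round(rng.normal(100, 8, 80)).astype(int))
    stats = spacer_distribution(values)
    assert len(stats.groups) == 1
    assert stats.groups[0][1] == 80


def test_spacer_distribution_split_overrides(rng):
    values = [60] * 10 + [140] * 10
    forced = spacer_distribution(values, split=100.0)
    assert forced.groups == [(60.0, 10), (140.0, 10)]
    none = spacer_distribution(values, split="none")
    assert len(none.groups) == 1


def test_spacer_distribution_rejects_empty():
    with pytest.raises(ValueError):
        spacer_distribution([])
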
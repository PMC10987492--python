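"""Motif scanning, the charge filter and family assignment."""

import re

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from arrestscreen.genome_io import GeneFeature
from arrestscreen.motifs import (
    PROTEOME_SCAN_PANEL,
    MotifHit,
    MotifQuery,
    assign_families,
    default_query_panel,
    load_query_panel,
    local_charge_profile,
    mifm_charge_filter,
    most_cterminal_diproline,
    proteome_rapp_scan,
    scan_cterm_motifs,
)
from arrestscreen.uorf_screen import UorfCandidate

from conftest import random_protein


def _naive_scan(protein, queries, default_window):
    """Independent regex restatement of the C-terminal scanning rules."""
    hits = set()
    for q in queries:
        regex = q.pattern.replace("x", ".")
        if q.anchor == "terminal":
            if re.search(regex + "$", protein) and len(protein) >= len(q.pattern):
                hits.add((q.pattern, len(protein) - len(q.pattern) + 1, len(protein)))
            continue
        window = q.window if q.window is not None else default_window
        for m in re.finditer(f"(?=({regex}))", protein):
            start, end = m.start() + 1, m.start() + len(q.pattern)
            if end > len(protein) - window:
                hits.add((q.pattern, start, end))
    return hits


def test_scan_finds_ywci_like_ragp_hit():
    protein = random_protein(__import__("numpy").random.default_rng(2), 87, "TNQHY") + "RAGP" + "TNQHYTNQH"
    assert len(protein) == 100
    hits = scan_cterm_motifs(protein, default_query_panel(), protein_id="ywcI")
    ragp = [h for h in hits if h.pattern == "RAGP"]
    assert [(h.match_start, h.match_end) for h in ragp] == [(88, 91)]


def test_scan_empty_without_panel_motif():
    assert scan_cterm_motifs("M" + "T" * 99, default_query_panel()) == []


def test_scan_respects_cterminal_window():
    protein = "M" + "RAPP" + "T" * 95  # motif far from the C-terminus
    assert scan_cterm_motifs(protein, default_query_panel(), window_len=30) == []
    assert scan_cterm_motifs(protein, default_query_panel(), window_len=99) != []


def test_terminal_anchor_matches_only_at_the_end():
    panel = [MotifQuery(pattern="NSP", anchor="terminal", klass="termination", code="NSP-stop")]
    assert scan_cterm_motifs("MTTTNSP", panel) != []
    assert scan_cterm_motifs("MTTTNSPT", panel) == []


def test_scan_matches_regex_oracle_on_seeded_proteins(rng):
    panel = default_query_panel()
    for _ in range(1000):
        protein = random_protein(rng, 150)
        got = {
            (h.pattern, h.match_start, h.match_end)
            for h in scan_cterm_motifs(protein, panel, window_len=30)
        }
        assert got == _naive_scan(protein, panel, 30)


def test_wildcard_matches_any_residue():
    panel = [MotifQuery(pattern="KYxIW", anchor="internal_cterm_window", klass="override", code="KYxIW")]
    for mid in "AGW":
        protein = "M" + "T" * 60 + f"KY{mid}IW" + "T" * 10
        hits = scan_cterm_motifs(protein, panel, window_len=30)
        assert [(h.match_start, h.match_end) for h in hits] == [(62, 66)]


@pytest.mark.parametrize(
    "protein,expected",
    [
        ("M" + "A" * 48 + "PP" + "A" * 28 + "PP" + "A" * 20, (80, 81)),
        ("M" + "A" * 99, None),
        ("M" + "A" * 56 + "PPP", (59, 60)),  # rightmost of the overlapping pair
    ],
)
def test_most_cterminal_diproline(protein, expected):
    hit = most_cterminal_diproline(protein)
    if expected is None:
        assert hit is None
    else:
        assert (hit.match_start, hit.match_end) == expected


@given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", max_size=60))
@settings(max_examples=300, deadline=None, derandomize=True)
def test_diproline_is_rightmost_occurrence(protein):
    hit = most_cterminal_diproline(protein)
    positions = [i + 1 for i in range(len(protein) - 1) if protein[i : i + 2] == "PP"]
    if not positions:
        assert hit is None
    else:
        assert hit.match_start == max(positions)
        assert hit.match_end == hit.match_start + 1


def test_local_charge_hand_values():
    profile = local_charge_profile("DDAAA")
    assert profile == [(3, -0.4)]
    assert all(c == 0 for _, c in local_charge_profile("A" * 20))


def test_local_charge_matches_brute_force(rng):
    protein = random_protein(rng, 90)
    scale = {"D": -1, "E": -1, "K": 1, "R": 1}
    for center, charge in local_charge_profile(protein):
        window = protein[center - 3 : center + 2]
        assert charge == pytest.approx(
            sum(scale.get(res, 0) for res in window) / 5
        )


def test_local_charge_short_protein_empty():
    assert local_charge_profile("MAD") == []


def test_mifm_filter_acidic_stretch():
    protein = "M" + "T" * 78 + "DEDEE" + "T" * 36  # DEDEE at 80-84
    assert len(protein) == 120
    assert mifm_charge_filter(protein)


def test_mifm_filter_no_acidic_region():
    assert not mifm_charge_filter("M" + "T" * 119)


def test_mifm_filter_boundary_window_means():
    # one D and one E in a 5-window: mean -0.4 < -0.3 passes
    two = "M" + "T" * 79 + "DE" + "T" * 38
    assert mifm_charge_filter(two)
    # a single D anywhere in the region: mean -0.2 fails
    one = "M" + "T" * 79 + "D" + "T" * 39
    assert not mifm_charge_filter(one)


def test_mifm_filter_short_protein_fails():
    assert not mifm_charge_filter("M" + "D" * 60)


def test_mifm_filter_is_monotone_under_acidification(rng):
    """Replacing any residue in the scored region by D or E never flips
    a passing protein to failing."""
    for _ in range(50):
        protein = random_protein(rng, 110)
        before = mifm_charge_filter(protein)
        pos = int(rng.integers(69, 100))
        acidified = protein[:pos] + "D" + protein[pos + 1 :]
        after = mifm_charge_filter(acidified)
        assert not (before and not after)


def _candidate(genome_id, locus, order, target_class="uA"):
    return UorfCandidate(
        genome_id=genome_id,
        taxonomy={"phylum": "P", "order": order},
        uorf_feature=GeneFeature("c", 1, 9, "+", locus, "hypothetical protein"),
        protein="MRGPPTT",
        target_class=target_class,
        target_locus_tag="t",
        intergenic_gap=100,
    )


def _hit(locus, code="RQH"):
    q = MotifQuery(pattern="RGPP", anchor="internal_cterm_window", klass="elongation", code=code)
    return MotifHit(
        protein_id=str(locus), pattern="RGPP", match_start=2, match_end=5,
        matched="RGPP", query=q,
    )


def test_assign_families_three_or_more_members_form_family():
    cands = {(f"g{i}", "u"): _candidate(f"g{i}", "u", "Pseudomonadales") for i in range(4)}
    hits = {k: _hit(k) for k in cands}
    fams = assign_families(hits, cands)
    assert len(fams) == 1
    fam = fams[0]
    assert fam.family_name == "uA_RQH_Pseudomonadales"
    assert not fam.orphan and len(fam.members) == 4


def test_assign_families_two_members_are_orphans():
    cands = {(f"g{i}", "u"): _candidate(f"g{i}", "u", "Rhizobiales") for i in range(2)}
    hits = {k: _hit(k) for k in cands}
    fams = assign_families(hits, cands)
    assert len(fams) == 1 and fams[0].orphan


def test_assign_families_empty():
    assert assign_families({}, {}) == []


def test_assign_families_requires_taxonomy():
    cand = _candidate("g1", "u", order="")
    cand.taxonomy = {"phylum": "P"}
    with pytest.raises(ValueError, match="g1"):
        assign_families({("g1", "u"): _hit("u")}, {("g1", "u"): cand})


def test_assign_families_is_permutation_invariant():
    cands = {(f"g{i}", "u"): _candidate(f"g{i}", "u", "Bacillales") for i in range(5)}
    hits = {k: _hit(k) for k in cands}
    fams1 = assign_families(hits, cands)
    rev_hits = dict(reversed(list(hits.items())))
    fams2 = assign_families(rev_hits, cands)
    assert [(f.family_name, f.members, f.orphan) for f in fams1] == [
        (f.family_name, f.members, f.orphan) for f in fams2
    ]


def test_proteome_scan_reports_all_occurrences(rng):
    protein = random_protein(rng, 87, "TNQHY") + "RAGP" + random_protein(rng, 9, "TNQHY")
    hits = proteome_rapp_scan({"ywcI": protein})
    assert [(h.pattern, h.match_start, h.match_end) for h in hits] == [("RAGP", 88, 91)]
    assert proteome_rapp_scan({"clean": "M" + "T" * 200}) == []


def test_proteome_scan_matches_regex_oracle(rng):
    for _ in range(200):
        protein = random_protein(rng, 120)
        got = {
            (h.match_start, h.pattern)
            for h in proteome_rapp_scan({"p": protein})
        }
        expected = set()
        for pattern in PROTEOME_SCAN_PANEL:
            for m in re.finditer(f"(?=({pattern}))", protein):
                expected.add((m.start() + 1, pattern))
        assert got == expected


def test_query_panel_round_trips_through_yaml(tmp_path):
    path = tmp_path / "panel.yaml"
    path.write_text(
        "- pattern: RAPP\n  code: RQH\n"
        "- pattern: NSP\n  anchor: terminal\n  class: termination\n  code: NSP-stop\n"
        "- pattern: LPPP\n  code: LPPP\n  window: 15\n"
    )
    panel = load_query_panel(path)
    assert [q.pattern for q in panel] == ["RAPP", "NSP", "LPPP"]
    assert panel[1].anchor == "terminal" and panel[1].klass == "termination"
    assert panel[2].window == 15
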
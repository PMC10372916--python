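"""Fold-change classification, summary fractions, per-protein tables."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from succinylome.differential import (
    DiffCall,
    call_items,
    classify,
    per_protein_site_table,
    summarize,
)
from succinylome.normalize import SiteQuantNorm
from succinylome.sitemap import KsuSiteKey


def _oracle(fc, thr=1.0):
    if fc > thr:
        return "up"
    if fc < -thr:
        return "down"
    return "unchanged"


def test_classify_boundaries():
    assert classify(1.07) == "up"  # ratio ~2.1, past the threshold
    assert classify(1.0) == "unchanged"  # exactly two-fold is NOT "more than"
    assert classify(-1.0) == "unchanged"
    assert classify(-1.001) == "down"
    with pytest.raises(ValueError):
        classify(0.5, threshold_log2=0.0)


def test_classify_grid_matches_piecewise_oracle():
    for i in range(601):
        fc = -3.0 + i * 0.01
        assert classify(fc) == _oracle(fc)


@given(st.lists(st.floats(-5, 5, allow_nan=False), min_size=1, max_size=60))
def test_partition_and_symmetry(fcs):
    calls = [classify(f) for f in fcs]
    n_up = calls.count("up")
    n_down = calls.count("down")
    assert n_up + n_down + calls.count("unchanged") == len(fcs)
    neg = [classify(-f) for f in fcs]
    assert neg.count("up") == n_down and neg.count("down") == n_up


@given(
    st.lists(st.floats(-5, 5, allow_nan=False), min_size=1, max_size=60),
    st.floats(0.1, 3.0),
    st.floats(0.0, 2.0),
)
def test_raising_threshold_never_adds_calls(fcs, thr, bump):
    n_lo = sum(1 for f in fcs if classify(f, thr) != "unchanged")
    n_hi = sum(1 for f in fcs if classify(f, thr + bump) != "unchanged")
    assert n_hi <= n_lo


def _calls_from_counts(n_up, n_down, n_total, prefix="P"):
    calls = []
    for i in range(n_up):
        calls.append(DiffCall(f"{prefix}{i}", 1.5, "up"))
    for i in range(n_up, n_up + n_down):
        calls.append(DiffCall(f"{prefix}{i}", -1.5, "down"))
    for i in range(n_up + n_down, n_total):
        calls.append(DiffCall(f"{prefix}{i}", 0.0, "unchanged"))
    return calls


def test_summarize_reproduces_study_scale_fractions():
    """Feeding the study-scale counts (36 up + 158 down of 2958 proteins;
    144 up + 1 down of 406 sites) reproduces the headline fractions."""
    protein_calls = _calls_from_counts(36, 158, 2958)
    site_keys = [KsuSiteKey(f"S{i // 3}", 5 + i) for i in range(406)]
    site_calls = (
        [DiffCall(site_keys[i], 1.5, "up") for i in range(144)]
        + [DiffCall(site_keys[144], -1.5, "down")]
        + [DiffCall(k, 0.0, "unchanged") for k in site_keys[145:]]
    )
    index = {k: k.protein_id for k in site_keys}
    rep = summarize(protein_calls, site_calls, index)
    assert rep.n_dep == 194
    assert rep.pct_dep == pytest.approx(6.5, abs=0.1)
    assert rep.pct_up == pytest.approx(1.2, abs=0.1)
    assert rep.pct_down == pytest.approx(5.3, abs=0.1)
    assert rep.n_site_diff == 145 and rep.n_site_diff_up == 144
    assert rep.pct_site_diff_of_quantified == pytest.approx(35.5, abs=0.1)
    assert rep.n_dep == rep.n_dep_up + rep.n_dep_down


def test_summarize_zero_denominator_gives_none():
    rep = summarize([], [], {})
    assert rep.pct_dep is None and rep.pct_site_diff_of_quantified is None


def test_summarize_ksu_protein_percent():
    # 2 proteins quantified at site level, 1 carries a differential site
    k1, k2, k3 = KsuSiteKey("A", 1), KsuSiteKey("A", 9), KsuSiteKey("B", 4)
    calls = [DiffCall(k1, 2.0, "up"), DiffCall(k2, 0.0, "unchanged"), DiffCall(k3, 0.2, "unchanged")]
    rep = summarize([], calls, {k: k.protein_id for k in (k1, k2, k3)})
    assert rep.n_ksu_protein_quantified == 2
    assert rep.n_ksu_protein_diff == 1
    assert rep.pct_ksu_protein_diff == 50.0


def _norm(pid, pos, log2):
    return SiteQuantNorm(
        site=KsuSiteKey(pid, pos),
        norm_log2_by_rep={1: log2},
        merged_log2=log2,
        n_reps=1,
    )


def test_per_protein_table_seven_sites_four_up():
    """A protein with seven identified sites of which four exceed the
    two-fold threshold yields a 7-row table with 4 rows marked up."""
    positions = [5, 76, 81, 118, 126, 232, 243]
    log2s = [1.4, 1.2, 0.3, 2.1, -0.2, 1.6, 0.8]  # synthetic ratios
    norms = [_norm("LDHA", p, v) for p, v in zip(positions, log2s)]
    calls = call_items({n.site: n.merged_log2 for n in norms})
    known = {5: ["ac"], 118: ["ub"]}
    table = per_protein_site_table("LDHA", norms, calls, known)
    assert len(table) == 7
    assert (table["call"] == "up").sum() == 4
    assert list(table["position"]) == positions  # ordered by residue
    assert table.loc[table["position"] == 118, "known_mods"].item() == "ub"


def test_per_protein_table_unknown_protein_empty():
    assert per_protein_site_table("NOPE", [], []).empty


def test_per_protein_table_rowcount_matches_recount():
    import random

    rng = random.Random(77)
    norms, calls = [], []
    for pid in ("A", "B", "C"):
        for pos in rng.sample(range(2, 200), rng.randint(0, 10)):
            n = _norm(pid, pos, rng.uniform(-3, 3))
            norms.append(n)
    calls = call_items({n.site: n.merged_log2 for n in norms})
    for pid in ("A", "B", "C"):
        expected = sum(1 for n in norms if n.site.protein_id == pid)
        assert len(per_protein_site_table(pid, norms, calls)) == expected


def test_call_items_skips_missing_values():
    calls = call_items({"A": 2.0, "B": None, "C": -0.1})
    assert {c.item_id for c in calls} == {"A", "C"}
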
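"""Localization filter cascade, compartment distribution, ranking."""

import random

import pytest

from succinylome.candidates import (
    FilterSpec,
    compartment_distribution,
    filter_candidates,
    rank_candidates,
)
from succinylome.differential import DiffCall
from succinylome.io_formats import AnnotationSet
from succinylome.sitemap import KsuSiteKey

ORDER = ["mitochondrion", "cytoplasm", "extracellular exosome", "nucleus"]


def test_filterspec_overlap_rejected():
    with pytest.raises(ValueError):
        FilterSpec(cytoplasm_terms=frozenset({"mitochondrion"}))


def test_distribution_all_cytoplasm():
    ann = AnnotationSet({f"P{i}": frozenset({"cytoplasm"}) for i in range(5)})
    d = compartment_distribution({f"P{i}" for i in range(5)}, ann, ORDER)
    assert d["cytoplasm"] == 100.0
    assert d["other"] == 0.0


def test_distribution_unannotated_pool_to_other():
    d = compartment_distribution({"P1", "P2"}, AnnotationSet(), ORDER)
    assert d["other"] == 100.0


def test_distribution_empty_protein_set_is_null():
    d = compartment_distribution(set(), AnnotationSet(), ORDER)
    assert all(v is None for v in d.values())


def test_distribution_first_match_and_sum():
    # a protein with both mito and cyto terms goes to the first bin only
    ann = AnnotationSet({"P1": frozenset({"cytoplasm", "mitochondrion"}), "P2": frozenset({"cytoplasm"})})
    d = compartment_distribution({"P1", "P2"}, ann, ORDER)
    assert d["mitochondrion"] == 50.0 and d["cytoplasm"] == 50.0
    assert sum(v for v in d.values()) == pytest.approx(100.0, abs=0.2)


def test_distribution_matches_recount_oracle():
    rng = random.Random(31)
    terms = ORDER + ["plasma membrane", "extracellular matrix"]
    for _ in range(30):
        pids = [f"P{i}" for i in range(rng.randint(1, 40))]
        ann = AnnotationSet(
            {p: frozenset(rng.sample(terms, rng.randint(0, 3))) for p in pids if rng.random() < 0.9}
        )
        d = compartment_distribution(set(pids), ann, ORDER)
        # oracle: exhaustive single-assignment recount
        counts = {c: 0 for c in ORDER + ["other"]}
        for p in pids:
            for c in ORDER:
                if c in ann.get(p):
                    counts[c] += 1
                    break
            else:
                counts["other"] += 1
        for c in counts:
            assert d[c] == pytest.approx(100.0 * counts[c] / len(pids), abs=0.051)


def _up(pid, pos, fc=2.0):
    return DiffCall(KsuSiteKey(pid, pos), fc, "up")


def test_exclude_term_vetoes_cytoplasmic_protein():
    """Mitochondrial annotation dominates: a cytoplasm+mitochondrion
    protein is excluded from the final candidate table."""
    ann = AnnotationSet(
        {"PM": frozenset({"cytoplasm", "mitochondrion"}), "PC": frozenset({"cytoplasm"})}
    )
    table = filter_candidates([_up("PM", 10), _up("PC", 20)], ann)
    assert table.n_proteins == 1
    assert set(table.rows["protein_id"]) == {"PC"}
    # the vetoed protein still counts in the cytoplasm stage tally
    assert table.stage_counts["cytoplasm"]["sites"] == 2
    assert table.stage_counts["final"]["sites"] == 1


def test_no_up_sites_empty_table():
    calls = [DiffCall(KsuSiteKey("P1", 5), 0.0, "unchanged")]
    table = filter_candidates(calls, AnnotationSet({"P1": frozenset({"cytoplasm"})}))
    assert table.n_sites == 0 and table.n_proteins == 0
    assert table.rows.empty


def _set_algebra_oracle(calls, ann, spec):
    up = {c.item_id for c in calls if c.call == "up"}
    has = lambda pid, ts: bool(ann.get(pid) & ts)
    s1 = {s for s in up if has(s.protein_id, spec.extracellular_terms) and not has(s.protein_id, spec.exclude_terms)}
    s2 = {s for s in up if has(s.protein_id, spec.cytoplasm_terms)}
    final = s1 | {s for s in s2 if not has(s.protein_id, spec.exclude_terms)}
    return s1, s2, final


def test_filter_matches_set_algebra_oracle():
    rng = random.Random(101)
    spec = FilterSpec()
    all_terms = [
        "cytoplasm", "mitochondrion", "mitochondrial matrix", "nucleus",
        "extracellular exosome", "extracellular matrix", "plasma membrane",
    ]
    for _ in range(100):
        pids = [f"P{i}" for i in range(rng.randint(1, 25))]
        ann = AnnotationSet({p: frozenset(rng.sample(all_terms, rng.randint(0, 3))) for p in pids})
        calls = []
        for p in pids:
            for pos in rng.sample(range(1, 300), rng.randint(0, 4)):
                fc = rng.uniform(-3, 3)
                calls.append(DiffCall(KsuSiteKey(p, pos), fc, "up" if fc > 1 else ("down" if fc < -1 else "unchanged")))
        table = filter_candidates(calls, ann, spec)
        s1, s2, final = _set_algebra_oracle(calls, ann, spec)
        assert table.stage_counts["extracellular"]["sites"] == len(s1)
        assert table.stage_counts["cytoplasm"]["sites"] == len(s2)
        assert set(zip(table.rows["protein_id"], table.rows["position"])) == {
            (s.protein_id, s.position) for s in final
        }
        # invariant: no candidate protein carries an exclude term
        for pid in table.rows["protein_id"]:
            assert not (ann.get(pid) & spec.exclude_terms)


def test_rank_single_protein():
    ann = AnnotationSet({"P1": frozenset({"cytoplasm"})})
    table = filter_candidates([_up("P1", 5)], ann)
    ranked = rank_candidates(table)
    assert list(ranked["protein_id"]) == ["P1"]
    assert list(ranked["rank"]) == [1]


def test_rank_more_sites_first():
    ann = AnnotationSet({"A": frozenset({"cytoplasm"}), "B": frozenset({"cytoplasm"})})
    calls = [_up("A", 1, 1.5), _up("A", 2, 1.6), _up("A", 3, 1.4), _up("A", 4, 1.2), _up("B", 1, 3.0), _up("B", 2, 3.1)]
    ranked = rank_candidates(filter_candidates(calls, ann))
    assert list(ranked["protein_id"]) == ["A"] * 4 + ["B"] * 2


def test_rank_matches_sort_oracle():
    rng = random.Random(55)
    for _ in range(20):
        pids = [f"P{i}" for i in range(rng.randint(1, 10))]
        ann = AnnotationSet({p: frozenset({"cytoplasm"}) for p in pids})
        calls = []
        for p in pids:
            for pos in rng.sample(range(1, 99), rng.randint(1, 5)):
                calls.append(_up(p, pos, rng.uniform(1.1, 4.0)))
        table = filter_candidates(calls, ann)
        ranked = rank_candidates(table)
        # oracle: independent comparison sort over per-protein stats
        stats = {}
        for c in calls:
            st = stats.setdefault(c.item_id.protein_id, [0, -99.0])
            st[0] += 1
            st[1] = max(st[1], c.log2fc)
        expected = sorted(stats, key=lambda p: (-stats[p][0], -stats[p][1], p))
        got = list(dict.fromkeys(ranked["protein_id"]))
        assert got == expected


def test_removing_include_term_never_increases_counts():
    ann = AnnotationSet(
        {
            "A": frozenset({"cytoplasm"}),
            "B": frozenset({"extracellular exosome"}),
            "C": frozenset({"extracellular matrix", "cytoplasm"}),
        }
    )
    calls = [_up("A", 1), _up("B", 2), _up("C", 3)]
    full = filter_candidates(calls, ann, FilterSpec())
    narrowed = filter_candidates(
        calls, ann, FilterSpec(extracellular_terms=frozenset({"extracellular exosome"}))
    )
    assert narrowed.n_sites <= full.n_sites
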
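from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, strategies as st

from kgforge.chem import (
    BioactivityRecord,
    ChemError,
    Fingerprint,
    assemble_compound_pool,
    cluster_compounds,
    filter_bioactivities,
    pchembl_from_concentration,
    select_diverse_compounds,
    tanimoto,
)
from kgforge.synthetic import SynthParams, generate_datastore


def fp(*bits: int, width: int = 64) -> Fingerprint:
    return Fingerprint(on_bits=frozenset(bits), width=width)


# ----------------------------------------------------------------- pchembl
@pytest.mark.parametrize(
    "value,unit,expected",
    [(10, "µM", 5.0), (1, "nM", 9.0), (1, "M", 0.0), (1, "mM", 3.0),
     (10, "uM", 5.0)],
)
def test_pchembl_from_concentration(value, unit, expected):
    assert pchembl_from_concentration(value, unit) == pytest.approx(expected)


def test_pchembl_rejects_nonpositive():
    with pytest.raises(ChemError):
        pchembl_from_concentration(0, "nM")
    with pytest.raises(ChemError):
        pchembl_from_concentration(1, "furlong")


# ---------------------------------------------------------------- tanimoto
def test_tanimoto_examples():
    assert tanimoto(fp(1, 2, 3), fp(2, 3, 4)) == pytest.approx(0.5)
    assert tanimoto(fp(1, 2), fp(1, 2)) == 1.0
    assert tanimoto(fp(1, 2), fp(3, 4)) == 0.0
    with pytest.raises(ChemError):
        tanimoto(fp(), fp())


@given(st.sets(st.integers(0, 63)), st.sets(st.integers(0, 63)))
def test_tanimoto_symmetric_and_bounded(a_bits, b_bits):
    if not a_bits and not b_bits:
        return
    a, b = fp(*a_bits), fp(*b_bits)
    t = tanimoto(a, b)
    assert 0.0 <= t <= 1.0
    assert t == tanimoto(b, a)
    assert (t == 1.0) == (a.on_bits == b.on_bits)


# -------------------------------------------------------------- clustering
def test_mutually_similar_compounds_form_one_cluster():
    fps = {"a": fp(1, 2, 3, 4), "b": fp(1, 2, 3, 5), "c": fp(1, 2, 4, 5)}
    assignment = cluster_compounds(fps, threshold=0.5)
    assert assignment.n_clusters == 1


def test_mutually_dissimilar_compounds_stay_singletons():
    fps = {"a": fp(1, 2, 3), "b": fp(10, 11, 12), "c": fp(20, 21, 22)}
    assignment = cluster_compounds(fps, threshold=0.5)
    assert assignment.n_clusters == 3


def test_member_representative_similarity_contract():
    rng = np.random.default_rng(5)
    fps = {
        f"c{i}": fp(*rng.choice(64, size=12, replace=False))
        for i in range(40)
    }
    assignment = cluster_compounds(fps, threshold=0.5)
    for cid, cluster in assignment.membership.items():
        rep = assignment.representatives[cluster]
        assert tanimoto(fps[cid], fps[rep]) >= 0.5 or cid == rep


def test_clustering_invariant_under_input_permutation():
    rng = np.random.default_rng(9)
    fps = {
        f"c{i}": fp(*rng.choice(64, size=10, replace=False))
        for i in range(30)
    }
    base = cluster_compounds(fps, threshold=0.5)
    items = list(fps.items())
    rng.shuffle(items)
    shuffled = cluster_compounds(dict(items), threshold=0.5)
    assert dict(base.membership) == dict(shuffled.membership)


def test_planted_scaffold_clusters_recovered(small_store):
    """Leader clustering at 0.5 recovers exactly the planted scaffold
    groups, matching the connected components of the similarity graph."""
    datastore, ground_truth = small_store
    planted = ground_truth["scaffold_clusters"]
    members = sorted(cid for group in planted.values() for cid in group)
    fps = {cid: datastore.compounds[cid].fingerprint for cid in members}
    assignment = cluster_compounds(fps, threshold=0.5)
    by_cluster: dict[str, set[str]] = {}
    for cid, cluster in assignment.membership.items():
        by_cluster.setdefault(cluster, set()).add(cid)
    recovered = {frozenset(v) for v in by_cluster.values()}
    assert recovered == {frozenset(g) for g in planted.values()}

    # oracle: exhaustive pairwise similarity graph, connected components
    parent = {c: c for c in members}

    def find(c):
        while parent[c] != c:
            parent[c] = parent[parent[c]]
            c = parent[c]
        return c

    for i, a in enumerate(members):
        for b in members[i + 1:]:
            if tanimoto(fps[a], fps[b]) >= 0.5:
                parent[find(a)] = find(b)
    components = {}
    for c in members:
        components.setdefault(find(c), set()).add(c)
    assert {frozenset(v) for v in components.values()} == recovered


# ----------------------------------------------------------------- filters
def test_filter_bioactivities_rules():
    records = [
        BioactivityRecord("c1", "p1", "IC50", 6.0),
        BioactivityRecord("c2", "p1", "GI50", 6.0),  # bad standard type
        BioactivityRecord("c3", "p1", "Ki", None),  # no pChEMBL
        BioactivityRecord("c4", "p1", "Ki", 4.5),  # below floor
        BioactivityRecord("c5", "p1", "Kd", 7.0, target_kind="complex"),
        BioactivityRecord("c6", "p1", "potency", 5.0, taxon_id=10090),
        BioactivityRecord("c7", "p1", "Potency", 5.0),
    ]
    kept = filter_bioactivities(records, taxa=(9606,), pchembl_min=5.0)
    assert [r.compound_id for r in kept] == ["c1", "c7"]


def test_filter_matches_brute_force_recount():
    rng = np.random.default_rng(2)
    types = ["IC50", "GI50", "Ki", "Kd"]
    records = [
        BioactivityRecord(
            f"c{i}", f"p{i % 7}", types[int(rng.integers(4))],
            None if rng.random() < 0.1 else float(4 + 6 * rng.random()),
            target_kind="single_protein" if rng.random() < 0.9 else "other",
            taxon_id=9606 if rng.random() < 0.8 else 10090,
        )
        for i in range(100)
    ]
    kept = filter_bioactivities(records, taxa=(9606,), pchembl_min=5)
    brute = [
        r for r in records
        if r.target_kind == "single_protein" and r.taxon_id == 9606
        and r.standard_type in ("IC50", "Ki", "Kd")
        and r.pchembl is not None and r.pchembl >= 5
    ]
    assert kept == brute


# -------------------------------------------------------------------- pool
def _records(spec: list[tuple[str, float]]) -> list[BioactivityRecord]:
    return [BioactivityRecord(cid, "PT1", "IC50", p) for cid, p in spec]


def test_pool_raises_cutoff_when_over_upper_bound():
    # 22 compounds at 8.2 plus 18 at 8.7: first run (cutoff 8) sees 40 > 25,
    # one raise lands at 18 within [10, 25]
    spec = [(f"a{i}", 8.2) for i in range(22)] + [
        (f"b{i}", 8.7) for i in range(18)
    ]
    pool = assemble_compound_pool(
        _records(spec), {"PT1"}, lower=10, upper=25,
    )
    assert pool.final_cutoff == pytest.approx(8.5)
    assert pool.iterations == 2
    assert len(pool.distinct_compounds) == 18
    assert pool.within_bounds


def test_pool_accepts_first_run_within_bounds():
    spec = [(f"a{i}", 8.3) for i in range(15)]
    pool = assemble_compound_pool(_records(spec), {"PT1"}, lower=10, upper=25)
    assert pool.final_cutoff == 8.0
    assert pool.iterations == 1
    assert pool.within_bounds


def test_pool_lowers_cutoff_until_lower_bound():
    spec = [(f"a{i}", 6.4) for i in range(12)]
    pool = assemble_compound_pool(_records(spec), {"PT1"}, lower=10, upper=25)
    # needs cutoff <= 6.4: 8 -> 7.5 -> 7 -> 6.5 -> 6
    assert pool.final_cutoff == pytest.approx(6.0)
    assert len(pool.distinct_compounds) == 12
    assert pool.within_bounds


def test_pool_floor_relaxation_flagged():
    spec = [(f"a{i}", 5.2) for i in range(3)]
    pool = assemble_compound_pool(_records(spec), {"PT1"}, lower=10, upper=25)
    assert pool.final_cutoff == pytest.approx(5.0)
    assert pool.floor_relaxed
    assert not pool.within_bounds
    assert len(pool.distinct_compounds) == 3
    assert all(r.pchembl >= 5.0 for r in pool.records)


def test_pool_empty_targets():
    pool = assemble_compound_pool(_records([("a", 8.0)]), set())
    assert pool.distinct_compounds == frozenset()
    assert not pool.within_bounds


@given(st.lists(st.floats(4.0, 10.0), min_size=1, max_size=60),
       st.integers(2, 8))
def test_pool_lands_in_bounds_when_reachable(pchembls, lower):
    upper = lower + 6
    records = _records([(f"c{i}", p) for i, p in enumerate(pchembls)])
    pool = assemble_compound_pool(records, {"PT1"}, lower=lower, upper=upper)
    grid = [5.0 + 0.5 * i for i in range(30)]
    reachable = any(
        lower <= sum(1 for p in pchembls if p >= c) <= upper for c in grid
    )
    if reachable:
        assert pool.within_bounds


# --------------------------------------------------------------- selection
def test_cluster_aware_selection_skips_represented_clusters():
    membership = {"c1": "k1", "c2": "k1", "c3": "k2"}
    assert select_diverse_compounds(["c1", "c2", "c3"], membership, 2) == [
        "c1", "c3",
    ]
    assert select_diverse_compounds(["c1", "c2"], membership, 5) == ["c1"]
    assert select_diverse_compounds(
        ["c1", "c3"], membership, 5, already_present_clusters={"k1"}
    ) == ["c3"]


def test_selection_matches_brute_force_greedy():
    rng = np.random.default_rng(4)
    membership = {f"c{i}": f"k{int(rng.integers(10))}" for i in range(50)}
    ranking = [f"c{i}" for i in range(50)]
    rng.shuffle(ranking)
    picked = select_diverse_compounds(ranking, membership, 10)
    # oracle: naive greedy walk
    seen, expected = set(), []
    for cid in ranking:
        if len(expected) == 10:
            break
        if membership[cid] not in seen:
            seen.add(membership[cid])
            expected.append(cid)
    assert picked == expected
    clusters = [membership[c] for c in picked]
    assert len(clusters) == len(set(clusters))
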
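import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from operonmerge._errors import ValidationError
from operonmerge.expression import ablim_distance, diel_calls
from operonmerge.instances import (
    build_negative_instances,
    build_positive_instances,
    featurize,
    featurize_candidates,
    find_merge_candidates,
)
from operonmerge.io_formats import OperonPrediction

from conftest import make_catalog, make_profile


def diel_profiles(gene_ids, phases, rng=None):
    """One sinusoidal profile per gene; phase None means flat (non-diel)."""
    t = np.arange(0.0, 24.0, 3.0)
    out = {}
    for gid, phase in zip(gene_ids, phases):
        if phase is None:
            values = np.zeros(8)
        else:
            values = np.sin(2 * np.pi * (t - phase) / 24.0)
        out[gid] = make_profile(gid, values)
    return out


def calls_for(profiles):
    return diel_calls(profiles)


# ---------------------------------------------------------------------------
# featurize


def test_featurize_single_distance():
    fv = featurize([0.4])
    assert (fv.d_min, fv.d_mean, fv.d_sd, fv.d_max) == (0.4, 0.4, 0.0, 0.4)


def test_featurize_hand_computed_sample_sd():
    fv = featurize([1, 2, 3, 4])
    # sample sd of 1..4 = sqrt(sum((x-2.5)^2)/3) = sqrt(5/3)
    assert fv.d_min == 1 and fv.d_max == 4
    assert fv.d_mean == pytest.approx(2.5)
    assert fv.d_sd == pytest.approx(math.sqrt(5.0 / 3.0))


def test_featurize_empty_error():
    with pytest.raises(ValidationError):
        featurize([])


@given(st.lists(st.floats(min_value=0, max_value=100), min_size=1, max_size=12), st.randoms())
def test_featurize_permutation_invariant_and_ordered(distances, random):
    fv1 = featurize(distances)
    shuffled = distances[:]
    random.shuffle(shuffled)
    assert featurize(shuffled) == fv1
    assert fv1.d_min <= fv1.d_mean <= fv1.d_max
    assert fv1.d_sd >= 0


# ---------------------------------------------------------------------------
# positive instances


def test_positive_single_pair_degenerate():
    profiles = diel_profiles(["g1", "g2"], [0.0, 6.0])
    priors = [OperonPrediction("P0001", ("g1", "g2"))]
    out = build_positive_instances(priors, profiles, calls_for(profiles))
    assert len(out) == 1
    fv = out[0].features
    assert fv.d_min == fv.d_mean == fv.d_max and fv.d_sd == 0.0


def test_positive_three_genes_stats_from_three_pairs():
    profiles = diel_profiles(["g1", "g2", "g3"], [0.0, 3.0, 9.0])
    priors = [OperonPrediction("P0001", ("g1", "g2", "g3"))]
    out = build_positive_instances(priors, profiles, calls_for(profiles))
    dists = [
        ablim_distance(profiles[a], profiles[b])
        for a, b in itertools.combinations(["g1", "g2", "g3"], 2)
    ]
    assert out[0].features == featurize(dists)


def test_positive_skips_no_diel_prior():
    profiles = diel_profiles(["g1", "g2"], [None, None])
    priors = [OperonPrediction("P0001", ("g1", "g2"))]
    assert build_positive_instances(priors, profiles, calls_for(profiles)) == []


def test_positive_skips_single_gene_and_missing_profile():
    profiles = diel_profiles(["g1", "g2"], [0.0, 6.0])
    priors = [
        OperonPrediction("P0001", ("g1",)),
        OperonPrediction("P0002", ("g2", "gX")),  # gX has no profile
    ]
    assert build_positive_instances(priors, profiles, calls_for(profiles)) == []


# ---------------------------------------------------------------------------
# negative instances


def test_negative_adjacent_opposite_strands():
    catalog = make_catalog("+-")
    profiles = diel_profiles(["g1", "g2"], [0.0, None])
    out = build_negative_instances(
        catalog, profiles, calls_for(profiles), size_policy="fixed:2"
    )
    assert len(out) == 1
    assert out[0].label == "negative"
    assert out[0].gene_ids == ("g1", "g2")


def test_negative_rejects_single_strand_window():
    catalog = make_catalog("+++")
    profiles = diel_profiles(["g1", "g2", "g3"], [0.0, 6.0, 12.0])
    assert (
        build_negative_instances(
            catalog, profiles, calls_for(profiles), size_policy="fixed:3"
        )
        == []
    )


def test_negative_instances_never_single_strand():
    catalog = make_catalog("+-+--+-+")
    gene_ids = [f"g{i}" for i in range(1, 9)]
    profiles = diel_profiles(gene_ids, [0.0, 3.0, 6.0, 9.0, 12.0, 15.0, 18.0, 21.0])
    out = build_negative_instances(
        catalog, profiles, calls_for(profiles), size_policy="fixed:2"
    )
    for inst in out:
        strands = {catalog.gene(g).strand for g in inst.gene_ids}
        assert strands == {"+", "-"}


def test_negative_alternating_fixture_matches_window_oracle():
    n = 100
    catalog = make_catalog("+-" * (n // 2))
    gene_ids = [f"g{i}" for i in range(1, n + 1)]
    profiles = diel_profiles(gene_ids, [float(3 * (i % 8)) for i in range(n)])
    calls = calls_for(profiles)
    out = build_negative_instances(catalog, profiles, calls, size_policy="fixed:2")

    # Exhaustive oracle: greedy non-overlapping scan over all rank windows.
    expected = []
    i = 0
    ordered = catalog.genes_in_contig("c1")
    while i + 2 <= n:
        window = ordered[i : i + 2]
        strands = {catalog.gene(g).strand for g in window}
        diel_ok = any(calls[g].is_diel for g in window)
        if strands == {"+", "-"} and diel_ok:
            expected.append(tuple(window))
            i += 2
        else:
            i += 1
    assert [inst.gene_ids for inst in out] == expected
    assert len(out) == 50


def test_negative_match_policy_requires_seed_and_sizes():
    catalog = make_catalog("+-")
    profiles = diel_profiles(["g1", "g2"], [0.0, None])
    calls = calls_for(profiles)
    with pytest.raises(ValidationError, match="seed"):
        build_negative_instances(
            catalog, profiles, calls, size_policy="match_positive_distribution",
            positive_sizes=[2, 2],
        )
    with pytest.raises(ValidationError, match="positive_sizes"):
        build_negative_instances(
            catalog, profiles, calls, size_policy="match_positive_distribution", seed=1
        )


def test_negative_bad_policy_error():
    catalog = make_catalog("+-")
    profiles = diel_profiles(["g1", "g2"], [0.0, None])
    with pytest.raises(ValidationError, match="size_policy"):
        build_negative_instances(
            catalog, profiles, calls_for(profiles), size_policy="bogus"
        )


# ---------------------------------------------------------------------------
# merge candidates


def fig1_setup():
    """Two adjacent 2-gene priors on one + strand, a diel gene in each."""
    catalog = make_catalog("++++")
    profiles = diel_profiles(["g1", "g2", "g3", "g4"], [0.0, None, 6.0, None])
    priors = [
        OperonPrediction("P0001", ("g1", "g2")),
        OperonPrediction("P0002", ("g3", "g4")),
    ]
    return catalog, profiles, priors


def test_candidate_fig1_case():
    catalog, profiles, priors = fig1_setup()
    out = find_merge_candidates(priors, catalog, calls_for(profiles))
    assert len(out) == 1
    cand = out[0]
    assert cand.prior1.operon_id == "P0001" and cand.prior2.operon_id == "P0002"
    assert set(cand.cross_pairs) == {
        ("g1", "g3"), ("g1", "g4"), ("g2", "g3"), ("g2", "g4"),
    }


def test_candidate_blocked_by_intervening_gene():
    catalog = make_catalog("+++++")
    profiles = diel_profiles(
        ["g1", "g2", "g3", "g4", "g5"], [0.0, None, None, 6.0, None]
    )
    priors = [
        OperonPrediction("P0001", ("g1", "g2")),
        OperonPrediction("P0002", ("g4", "g5")),  # g3 intervenes
    ]
    assert find_merge_candidates(priors, catalog, calls_for(profiles)) == []


def test_candidate_blocked_by_strand():
    catalog = make_catalog("++--")
    profiles = diel_profiles(["g1", "g2", "g3", "g4"], [0.0, None, 6.0, None])
    priors = [
        OperonPrediction("P0001", ("g1", "g2")),
        OperonPrediction("P0002", ("g3", "g4")),
    ]
    assert find_merge_candidates(priors, catalog, calls_for(profiles)) == []


def test_candidate_blocked_by_missing_diel():
    catalog, profiles, priors = fig1_setup()
    profiles = diel_profiles(["g1", "g2", "g3", "g4"], [0.0, None, None, None])
    assert find_merge_candidates(priors, catalog, calls_for(profiles)) == []


def test_candidate_features_use_cross_pairs_only():
    catalog, profiles, priors = fig1_setup()
    calls = calls_for(profiles)
    cands = featurize_candidates(
        find_merge_candidates(priors, catalog, calls), profiles
    )
    cross = [
        ablim_distance(profiles[a], profiles[b])
        for a, b in [("g1", "g3"), ("g1", "g4"), ("g2", "g3"), ("g2", "g4")]
    ]
    assert cands[0].features == featurize(cross)
    # All 6 within+cross pairs would give different statistics.
    all_pairs = [
        ablim_distance(profiles[a], profiles[b])
        for a, b in itertools.combinations(["g1", "g2", "g3", "g4"], 2)
    ]
    assert cands[0].features != featurize(all_pairs)


def test_candidate_single_gene_priors_allowed():
    catalog = make_catalog("++")
    profiles = diel_profiles(["g1", "g2"], [0.0, 6.0])
    priors = [OperonPrediction("P0001", ("g1",)), OperonPrediction("P0002", ("g2",))]
    out = find_merge_candidates(priors, catalog, calls_for(profiles))
    assert len(out) == 1
    assert out[0].cross_pairs == (("g1", "g2"),)


def test_candidate_discovery_matches_brute_force(rng):
    # 40-gene random-strand catalog covered by random-length priors.
    n = 40
    strands = "".join(rng.choice(["+", "-"], size=n))
    catalog = make_catalog(strands)
    gene_ids = [f"g{i}" for i in range(1, n + 1)]
    phases = [float(p) if rng.random() < 0.7 else None for p in rng.uniform(0, 24, n)]
    profiles = diel_profiles(gene_ids, phases)
    calls = calls_for(profiles)
    priors = []
    i = 0
    while i < n:
        size = int(rng.integers(1, 4))
        run = [gene_ids[i]]
        j = i + 1
        while j < n and len(run) < size and strands[j] == strands[i]:
            run.append(gene_ids[j])
            j += 1
        priors.append(OperonPrediction(f"P{len(priors) + 1:04d}", tuple(run)))
        i = j
    out = find_merge_candidates(priors, catalog, calls)

    expected = []
    for p1, p2 in itertools.permutations(priors, 2):
        last1 = catalog.rank(p1.gene_ids[-1])
        first2 = catalog.rank(p2.gene_ids[0])
        all_genes = p1.gene_ids + p2.gene_ids
        if (
            last1 + 1 == first2
            and len({catalog.gene(g).strand for g in all_genes}) == 1
            and any(calls[g].is_diel for g in p1.gene_ids)
            and any(calls[g].is_diel for g in p2.gene_ids)
        ):
            expected.append((p1.operon_id, p2.operon_id))
    got = [(c.prior1.operon_id, c.prior2.operon_id) for c in out]
    assert sorted(got) == sorted(expected)
    # deterministic and sorted by rank
    ranks = [catalog.rank(c.prior1.gene_ids[0]) for c in out]
    assert ranks == sorted(ranks)


def test_candidate_gene_set_is_union_with_no_intervening_ranks():
    catalog, profiles, priors = fig1_setup()
    out = find_merge_candidates(priors, catalog, calls_for(profiles))
    cand = out[0]
    ranks = sorted(catalog.rank(g) for g in cand.gene_ids)
    assert ranks == list(range(ranks[0], ranks[0] + len(ranks)))
    assert set(cand.gene_ids) == set(cand.prior1.gene_ids) | set(cand.prior2.gene_ids)


def test_featurize_candidates_drops_missing_profiles():
    catalog, profiles, priors = fig1_setup()
    calls = calls_for(profiles)
    del profiles["g2"]
    cands = find_merge_candidates(priors, catalog, calls)
    assert featurize_candidates(cands, profiles) == []
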
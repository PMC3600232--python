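import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rindom import (
    Domain,
    DomainAnnotation,
    Method,
    NetworkBuildConfig,
    Partition,
    UndefinedAccuracyError,
    VertexStrategy,
    accuracy,
    aggregate_accuracy,
    evaluate_structure,
    label_residues,
    read_annotation_tsv,
    write_annotation_tsv,
)

from conftest import make_network


def two_domain_annotation():
    return DomainAnnotation(
        "test",
        [
            Domain("d1", [("A", 10, "", 100, "")]),
            Domain("d2", [("A", 101, "", 200, "")]),
        ],
    )


class TestLabelResidues:
    def test_residue_inside_and_outside_ranges(self):
        ann = two_domain_annotation()
        net = make_network(3, [])
        net.vertices = [("A", 42, ""), ("A", 5, ""), ("A", 150, "")]
        assert label_residues(net, ann) == ["d1", None, "d2"]

    def test_range_bounds_inclusive(self):
        ann = DomainAnnotation("t", [Domain("d1", [("A", 10, "", 20, "")])])
        net = make_network(4, [])
        net.vertices = [("A", 9, ""), ("A", 10, ""), ("A", 20, ""), ("A", 21, "")]
        assert label_residues(net, ann) == [None, "d1", "d1", None]

    def test_insertion_code_range(self):
        ann = DomainAnnotation("t", [Domain("d1", [("A", 100, "A", 100, "C")])])
        net = make_network(5, [])
        net.vertices = [
            ("A", 100, ""), ("A", 100, "A"), ("A", 100, "B"),
            ("A", 100, "C"), ("A", 100, "D"),
        ]
        assert label_residues(net, ann) == [None, "d1", "d1", "d1", None]

    def test_absent_chain_warns_and_skips(self, caplog):
        ann = DomainAnnotation("t", [
            Domain("d1", [("A", 1, "", 5, "")]),
            Domain("d2", [("B", 1, "", 5, "")]),
        ])
        net = make_network(2, [])
        net.vertices = [("A", 1, ""), ("A", 2, "")]
        with caplog.at_level("WARNING"):
            labels = label_residues(net, ann)
        assert labels == ["d1", "d1"]
        assert any("absent chain B" in m for m in caplog.messages)


class TestAccuracy:
    def test_ninety_of_hundred_domain_residues_gives_90_percent(self):
        # two 50-residue domains; 45 of each land in the community matched to
        # their domain, the stray 10 residues end up in the opposite community
        labels = ["d1"] * 50 + ["d2"] * 50
        part = np.array([0] * 45 + [1] * 5 + [1] * 45 + [0] * 5)
        result = accuracy(Partition(part), labels)
        assert result.accuracy == pytest.approx(90.0)
        assert result.n_domain_residues == 100
        assert result.matching == {0: "d1", 1: "d2"}

    def test_perfect_partition_is_100_percent(self):
        labels = ["d1"] * 10 + ["d2"] * 15 + [None] * 3
        part = np.array([7] * 10 + [2] * 15 + [7] * 3)  # linker ignored
        assert accuracy(Partition(np.array(
            [0] * 10 + [1] * 15 + [0] * 3
        )), labels).accuracy == pytest.approx(100.0)

    def test_single_community_covering_two_domains_scores_half(self):
        labels = ["d1"] * 10 + ["d2"] * 10
        part = Partition(np.zeros(20, dtype=int))
        result = accuracy(part, labels)
        assert result.accuracy == pytest.approx(50.0)
        assert len(result.matching) == 1

    def test_matching_is_injective_and_optimal_for_small_cases(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            n_dom = int(rng.integers(2, 6))
            n_comm = int(rng.integers(1, 7))
            n_res = int(rng.integers(n_dom, 40))
            labels = [f"d{rng.integers(n_dom)}" for _ in range(n_res)]
            part = Partition(
                np.array([rng.integers(n_comm) for _ in range(n_res)])
            )
            result = accuracy(part, labels)
            doms = sorted(set(labels))
            counts = {
                (c, d): sum(
                    1 for lab, com in zip(labels, part.labels)
                    if lab == d and com == c
                )
                for c in range(part.n_communities)
                for d in doms
            }
            n_comm_eff = part.n_communities
            if n_comm_eff <= len(doms):
                best = max(
                    sum(counts[c, d] for c, d in zip(range(n_comm_eff), ds))
                    for ds in itertools.permutations(doms, n_comm_eff)
                )
            else:
                best = max(
                    sum(counts[c, d] for c, d in zip(cs, doms))
                    for cs in itertools.permutations(range(n_comm_eff), len(doms))
                )
            assert result.accuracy == pytest.approx(100.0 * best / n_res)
            matched_doms = list(result.matching.values())
            assert len(matched_doms) == len(set(matched_doms))

    @settings(max_examples=30, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_relabeling_invariance(self, seed):
        rng = np.random.default_rng(seed)
        n = 30
        labels = [f"d{rng.integers(3)}" if rng.uniform() > 0.2 else None
                  for _ in range(n)]
        if not any(labels):
            labels[0] = "d0"
        raw = np.array([rng.integers(4) for _ in range(n)])
        base = accuracy(Partition(_normalize(raw)), labels).accuracy
        # permute community ids
        perm = rng.permutation(4)
        permuted = _normalize(np.array([perm[c] for c in raw]))
        assert accuracy(Partition(permuted), labels).accuracy == pytest.approx(base)
        # permute domain ids
        name_map = dict(zip(["d0", "d1", "d2"], ["x", "y", "z"]))
        relabeled = [name_map.get(l) if l else None for l in labels]
        assert accuracy(Partition(_normalize(raw)), relabeled).accuracy == (
            pytest.approx(base)
        )

    def test_majority_mapping_can_reuse_domains(self):
        labels = ["d1"] * 10 + ["d2"] * 2
        part = Partition(np.array([0] * 6 + [1] * 6))
        strict = accuracy(part, labels, mapping="matching")
        loose = accuracy(part, labels, mapping="majority")
        assert strict.accuracy == pytest.approx(100.0 * 8 / 12)
        assert loose.accuracy == pytest.approx(100.0 * 10 / 12)

    def test_no_domain_residues_is_undefined(self):
        with pytest.raises(UndefinedAccuracyError):
            accuracy(Partition(np.array([0, 1])), [None, None])


def _normalize(raw):
    seen = {}
    return np.array([seen.setdefault(c, len(seen)) for c in raw])


class TestEvaluateStructure:
    def test_two_domain_synthetic_recovered_exactly(self, synthetic_two_domain):
        model, ann = synthetic_two_domain
        result = evaluate_structure(
            model, ann, NetworkBuildConfig(VertexStrategy.CA, 5.0),
            Method.EDGE_BETWEENNESS,
        )
        assert result.accuracy == pytest.approx(100.0)
        assert result.k == 2

    def test_edgeless_network_scores_near_zero(self, synthetic_two_domain):
        model, ann = synthetic_two_domain
        result = evaluate_structure(
            model, ann, NetworkBuildConfig(VertexStrategy.CA, 3.0),
            Method.EDGE_BETWEENNESS,
        )
        # singleton partition: one residue matched per domain
        assert result.accuracy == pytest.approx(100.0 * 2 / result.n_domain_residues)

    def test_repeat_evaluation_is_identical(self, synthetic_two_domain):
        model, ann = synthetic_two_domain
        cfg = NetworkBuildConfig(VertexStrategy.CENTROID, 7.0)
        r1 = evaluate_structure(model, ann, cfg, Method.RANDOM_WALK, steps=5)
        r2 = evaluate_structure(model, ann, cfg, Method.RANDOM_WALK, steps=5)
        assert r1 == r2


def test_aggregate_accuracy_modes():
    from rindom import EvaluationResult

    results = [
        EvaluationResult("a", 80.0, 100),
        EvaluationResult("b", 100.0, 300),
    ]
    assert aggregate_accuracy(results) == pytest.approx(90.0)
    assert aggregate_accuracy(results, weighted=True) == pytest.approx(95.0)


def test_annotation_tsv_round_trip(tmp_path):
    ann = DomainAnnotation("1abc", [
        Domain("d1", [("A", 1, "", 50, ""), ("A", 120, "", 160, "B")]),
        Domain("d2", [("A", 51, "", 119, "")]),
    ])
    path = tmp_path / "ann.tsv"
    write_annotation_tsv([ann], path)
    loaded = read_annotation_tsv(path)["1abc"]
    assert [d.domain_id for d in loaded.domains] == ["d1", "d2"]
    assert loaded.domains[0].ranges == ann.domains[0].ranges
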
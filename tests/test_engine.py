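"""The counterfactual condition, clustering, selection, and the end-to-end
explanation pipeline."""

import numpy as np
import pytest
from rdkit import Chem

import molcf
from molcf.engine import (
    ExplanationCandidate,
    PredictorError,
    cluster_candidates,
    is_counterfactual,
    project_space,
    result_to_csv,
    select_counterfactuals,
)
from molcf.fixtures import (
    CARBOXYLIC_ACID,
    constant_predictor,
    heavy_atom_regressor,
    lookup_predictor,
    substructure_classifier,
)
from molcf.molecules import Fingerprint, MoleculeRecord

from dbscan_oracle import brute_force_dbscan, equivalent_labelings


def _fake_candidate(bits, similarity=0.5, n_bits=64, smiles="C", output=0):
    record = MoleculeRecord(
        input_smiles=smiles, canonical_smiles=smiles, selfies="[C]",
        fingerprint=Fingerprint(bits=frozenset(bits), n_bits=n_bits))
    return ExplanationCandidate(record=record, similarity=similarity,
                                output=output, is_counterfactual=True)


# --- counterfactual condition ------------------------------------------------

@pytest.mark.parametrize("cand,base,mode,delta,expect,direction", [
    (1, 0, "classification", None, True, 0),
    (0, 0, "classification", None, False, 0),
    ("active", "inactive", "classification", None, True, 0),
    (-0.5, -2.0, "regression", 1.0, True, 1),   # increase of 1.5 >= 1
    (-1.5, -2.0, "regression", 1.0, False, 0),  # change of 0.5 < 1
    (-3.0, -2.0, "regression", 1.0, True, -1),  # decrease of 1.0 >= 1
    (5.0, 5.0, "regression", 1.0, False, 0),
])
def test_counterfactual_condition(cand, base, mode, delta, expect, direction):
    assert is_counterfactual(cand, base, mode, delta) == (expect, direction)


def test_regression_requires_positive_delta():
    with pytest.raises(ValueError):
        is_counterfactual(1.0, 0.0, "regression", None)
    with pytest.raises(ValueError):
        is_counterfactual(1.0, 0.0, "regression", -1.0)


# --- clustering --------------------------------------------------------------

def test_identical_fingerprints_form_one_cluster():
    cands = [_fake_candidate({1, 2, 3}) for _ in range(6)]
    labels = cluster_candidates(cands, eps=0.15, min_samples=5)
    assert set(labels) == {0}


def test_two_distant_groups_form_two_clusters():
    group_a = [_fake_candidate({1, 2, 3}) for _ in range(6)]
    group_b = [_fake_candidate({10, 11, 12, 13}) for _ in range(6)]
    labels = cluster_candidates(group_a + group_b, eps=0.15, min_samples=5)
    assert len(set(labels)) == 2 and -1 not in set(labels)
    assert len(set(labels[:6])) == 1 and len(set(labels[6:])) == 1


def test_too_few_points_are_all_noise():
    cands = [_fake_candidate({1, 2, 3}) for _ in range(3)]
    assert list(cluster_candidates(cands, min_samples=5)) == [-1, -1, -1]


def test_empty_candidate_list_yields_empty_labels():
    assert len(cluster_candidates([])) == 0


def test_eps_outside_unit_interval_is_rejected():
    with pytest.raises(ValueError):
        cluster_candidates([_fake_candidate({1})], eps=1.5)


def test_clustering_matches_brute_force_oracle_on_random_instances():
    """Engine labels equal an independently written DBSCAN on 200 random
    <=15-point instances at eps=0.15, min_samples=5."""
    rng = np.random.default_rng(42)
    checked_all_noise = checked_clustered = 0
    for _ in range(200):
        n = int(rng.integers(1, 16))
        n_bits = 64
        # random fingerprints with correlated bits so some pairs are close
        seeds = [frozenset(rng.choice(n_bits, size=8, replace=False).tolist())
                 for _ in range(max(1, n // 5))]
        cands = []
        for _ in range(n):
            base = set(rng.permuted(list(seeds[int(rng.integers(len(seeds)))])))
            if rng.random() < 0.5:
                base.add(int(rng.integers(n_bits)))
            cands.append(_fake_candidate(base, n_bits=n_bits))
        labels = cluster_candidates(cands, eps=0.15, min_samples=5)
        dist = [[molcf.distance(a.record.fingerprint, b.record.fingerprint)
                 for b in cands] for a in cands]
        oracle = brute_force_dbscan(dist, eps=0.15, min_samples=5)
        assert equivalent_labelings(labels, oracle)
        if set(oracle) == {-1}:
            checked_all_noise += 1
        elif -1 not in set(oracle):
            checked_clustered += 1
    # the corners the oracle must cover actually occurred
    assert checked_all_noise > 0 and checked_clustered > 0


# --- selection ---------------------------------------------------------------

def test_selection_picks_most_similar_member_per_cluster():
    cands = [_fake_candidate({1}, s) for s in (0.6, 0.8, 0.7)]
    chosen = select_counterfactuals(cands, np.array([0, 0, 0]), n_requested=3)
    assert len(chosen) == 1 and chosen[0].similarity == 0.8


def test_selection_truncates_to_most_similar_representatives():
    cands = [_fake_candidate({i}, s) for i, s in enumerate((0.9, 0.5, 0.7, 0.6))]
    chosen = select_counterfactuals(cands, np.array([0, 1, 2, 3]), n_requested=3)
    assert [c.similarity for c in chosen] == [0.9, 0.7, 0.6]


def test_selection_tops_up_from_noise_and_sorts_descending():
    cands = [_fake_candidate({1}, 0.8), _fake_candidate({2}, 0.75),
             _fake_candidate({3}, 0.9), _fake_candidate({4}, 0.3)]
    chosen = select_counterfactuals(cands, np.array([0, 0, -1, -1]), n_requested=3)
    assert [c.similarity for c in chosen] == [0.9, 0.8, 0.3]


def test_selection_tie_breaks_on_lexicographic_smiles():
    a = _fake_candidate({1}, 0.8, smiles="CCO")
    b = _fake_candidate({2}, 0.8, smiles="CCN")
    chosen = select_counterfactuals([a, b], np.array([0, 0]), n_requested=1)
    assert chosen[0].record.canonical_smiles == "CCN"


def test_selection_of_nothing_is_empty():
    assert select_counterfactuals([], np.empty(0, dtype=int), 3) == []
    with pytest.raises(ValueError):
        select_counterfactuals([], np.empty(0, dtype=int), 0)


# --- end-to-end --------------------------------------------------------------

@pytest.fixture(scope="module")
def acid_result(acid_base):
    return molcf.explain(
        acid_base.canonical_smiles, substructure_classifier(),
        molcf.SamplerConfig(num_samples=400, seed=7))


def test_counterfactuals_of_acid_classifier_lack_the_acid(acid_result):
    pattern = Chem.MolFromSmarts(CARBOXYLIC_ACID)
    assert acid_result.base.output == 1
    assert acid_result.counterfactuals
    for cand in acid_result.counterfactuals:
        assert cand.output == 0 and cand.is_counterfactual
        assert not Chem.MolFromSmiles(cand.record.canonical_smiles).HasSubstructMatch(pattern)


def test_every_returned_counterfactual_satisfies_the_condition(acid_result):
    for cand in acid_result.all_candidates:
        assert cand.is_counterfactual == (cand.output != acid_result.base.output)
    for cand in acid_result.counterfactuals:
        assert cand.is_counterfactual
        assert 0 <= cand.similarity < 1


def test_counterfactuals_sorted_by_similarity(acid_result):
    sims = [c.similarity for c in acid_result.counterfactuals]
    assert sims == sorted(sims, reverse=True)


def test_representative_optimality(acid_result):
    """No unreturned cluster member outranks its returned representative."""
    cf = [c for c in acid_result.all_candidates if c.is_counterfactual]
    returned = {c.record.canonical_smiles: c for c in acid_result.counterfactuals}
    for cand in cf:
        if cand.cluster_id == -1:
            continue
        rep = next((r for r in acid_result.counterfactuals
                    if r.cluster_id == cand.cluster_id), None)
        if rep is not None:
            assert cand.similarity <= rep.similarity or \
                cand.record.canonical_smiles in returned


def test_heavy_atom_regression_counterfactuals_change_count():
    result = molcf.explain(
        "CCCCCC", heavy_atom_regressor(),
        molcf.SamplerConfig(num_samples=300, seed=3), delta=1.0)
    assert result.base.output == 6.0
    assert result.counterfactuals
    for cand in result.counterfactuals:
        count = Chem.MolFromSmiles(cand.record.canonical_smiles).GetNumHeavyAtoms()
        assert count <= 5 or count >= 7
        assert cand.direction == (1 if count > 6 else -1)


def test_constant_predictor_yields_empty_list_with_advice():
    for predictor, delta in ((constant_predictor(1), None),
                             (constant_predictor(0.0, mode="regression"), 1.0)):
        result = molcf.explain("CCO", predictor,
                               molcf.SamplerConfig(num_samples=100, seed=1),
                               delta=delta)
        assert result.counterfactuals == []
        assert "advice" in result.diagnostics


def test_lookup_table_and_code_produce_identical_results(acid_base):
    """Model-agnosticism probe: an opaque lookup table of the classifier's
    outputs must reproduce the code-defined classifier bit for bit."""
    config = molcf.SamplerConfig(num_samples=200, seed=11)
    classifier = substructure_classifier()
    candidates, _ = molcf.expand_space(acid_base, config)
    smiles = [acid_base.canonical_smiles] + [c.canonical_smiles for c in candidates]
    table = dict(zip(smiles, classifier(smiles)))

    res_code = molcf.explain(acid_base.canonical_smiles, classifier, config)
    res_table = molcf.explain(acid_base.canonical_smiles,
                              lookup_predictor(table), config)
    assert molcf.result_to_csv(res_code) == molcf.result_to_csv(res_table)
    assert [c.record.canonical_smiles for c in res_code.counterfactuals] == \
        [c.record.canonical_smiles for c in res_table.counterfactuals]


def test_best_similarity_non_decreasing_in_sample_size():
    """A larger sample is a superset under nested seeds, so the best
    counterfactual similarity can only improve."""
    best = []
    for n in (50, 200):
        result = molcf.explain("CCCCCC", heavy_atom_regressor(),
                               molcf.SamplerConfig(num_samples=n, seed=2),
                               delta=1.0)
        best.append(max((c.similarity for c in result.counterfactuals),
                        default=0.0))
    assert best[0] <= best[1]


def test_predictor_contract_violations_are_named():
    broken = molcf.PredictorContract(predict=lambda batch: [0], mode="classification")
    with pytest.raises(PredictorError, match="outputs"):
        molcf.explain("CCO", broken, molcf.SamplerConfig(num_samples=20, seed=0))
    with pytest.raises(ValueError, match="delta"):
        molcf.explain("CCO", heavy_atom_regressor(),
                      molcf.SamplerConfig(num_samples=20, seed=0))


def test_nonfinite_regression_outputs_are_discarded():
    def predict(batch):
        # base is index 0 and stays finite; odd candidates are NaN
        return [float(i) if i % 2 == 0 else float("nan") for i in range(len(batch))]

    base = molcf.parse_molecule("CCO")
    candidates, _ = molcf.expand_space(base, molcf.SamplerConfig(num_samples=20, seed=0))
    result = molcf.explain_space(
        base, candidates,
        molcf.PredictorContract(predict=predict, mode="regression"), delta=1.0)
    assert result.diagnostics["nonfinite_outputs_discarded"] > 0
    assert all(c.is_counterfactual is not None for c in result.all_candidates)


def test_base_prediction_nonfinite_is_an_error():
    base = molcf.parse_molecule("CCO")
    bad = molcf.PredictorContract(
        predict=lambda batch: [float("nan")] * len(batch), mode="regression")
    with pytest.raises(PredictorError, match="base"):
        molcf.explain_space(base, [], bad, delta=1.0)


# --- projection --------------------------------------------------------------

def test_projection_reproduces_three_point_distances_exactly():
    cands = [_fake_candidate({1, 2, 3, 4}),
             _fake_candidate({1, 2, 3, 8}),
             _fake_candidate({1, 8, 9, 10})]
    coords = project_space(cands)
    assert coords.shape == (3, 2)
    for i in range(3):
        for j in range(3):
            want = molcf.distance(cands[i].record.fingerprint,
                                  cands[j].record.fingerprint)
            got = float(np.linalg.norm(coords[i] - coords[j]))
            assert got == pytest.approx(want, abs=1e-9)


def test_collinear_distances_project_onto_one_axis():
    # d(A,B) = d(B,C) = 0.5 and d(A,C) = 1.0: a perfect 1-D gradient
    cands = [_fake_candidate({1, 2, 3}),
             _fake_candidate({1, 2, 3, 4, 5, 6}),
             _fake_candidate({4, 5, 6})]
    coords = project_space(cands)
    assert np.allclose(coords[:, 1], 0.0, atol=1e-7)
    # rank order of distances to the first point is preserved
    d = np.linalg.norm(coords - coords[0], axis=1)
    assert d[0] < d[1] < d[2]


def test_projection_degenerate_and_small_inputs():
    same = [_fake_candidate({1, 2}) for _ in range(4)]
    assert np.allclose(project_space(same), 0.0)
    two_groups = [_fake_candidate({1, 2}), _fake_candidate({1, 2}),
                  _fake_candidate({5, 6}), _fake_candidate({5, 6})]
    coords = project_space(two_groups)
    assert np.allclose(coords[0], coords[1]) and np.allclose(coords[2], coords[3])
    assert not np.allclose(coords[0], coords[2])
    with pytest.raises(ValueError):
        project_space(same[:2])


def test_projection_sign_convention_is_deterministic():
    cands = [_fake_candidate({i, i + 1, i + 2}) for i in (1, 4, 7, 10)]
    a, b = project_space(cands), project_space(cands)
    assert np.array_equal(a, b)
    for axis in range(2):
        col = a[:, axis]
        assert col[np.argmax(np.abs(col))] >= 0


# --- writers -----------------------------------------------------------------

def test_csv_writer_layout(acid_result):
    text = result_to_csv(acid_result, "counterfactuals")
    lines = text.splitlines()
    assert lines[0] == "canonical_smiles,selfies,similarity,output,is_counterfactual,cluster_id"
    assert lines[1].startswith(acid_result.base.record.canonical_smiles)
    assert len(lines) == 2 + len(acid_result.counterfactuals)


def test_json_writer_round_trips(acid_result):
    import json

    doc = json.loads(molcf.result_to_json(acid_result))
    assert doc["mode"] == "classification"
    assert doc["base"]["similarity"] == 1.0
    assert len(doc["counterfactuals"]) == len(acid_result.counterfactuals)
    assert doc["parameters"]["eps"] == 0.15
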
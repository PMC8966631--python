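"""Counterfactual search over an enumerated chemical space.

Given a black-box predictor f̂ and a base molecule x, a counterfactual x' is
the closest molecule whose prediction differs:

* classification — f̂(x') ≠ f̂(x);
* regression — |f̂(x') − f̂(x)| ≥ Δ, where Δ is the problem-specific minimum
  change of interest (both directions qualify, the sign is annotated).

Because molecules are discrete, the constrained minimization of distance is
realized as an argmax of Tanimoto similarity over the sampled space.  To
return a *diverse* handful rather than near-duplicates of one modification,
the counterfactual subset is clustered with DBSCAN on the Tanimoto distance
matrix (d = 1 − s, ε = 0.15, 5 samples minimum) and the most similar member
of each cluster is selected.

The predictor is consulted exactly once per explanation, with the full
candidate batch — nothing else about the model is observed (no gradients, no
architecture): an opaque lookup table and an equivalent function produce
identical results.
"""

from __future__ import annotations

import csv
import dataclasses
import io
import json
import math
from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np
from sklearn.cluster import DBSCAN

from . import __version__
from .molecules import (
    CANONICALIZER,
    MoleculeRecord,
    distance,
    parse_molecule,
    tanimoto,
)
from .sampler import SampleDiagnostics, SamplerConfig, expand_space

__all__ = [
    "PredictorContract",
    "PredictorError",
    "ExplanationCandidate",
    "ExplanationResult",
    "is_counterfactual",
    "cluster_candidates",
    "select_counterfactuals",
    "explain",
    "explain_space",
    "project_space",
    "result_to_csv",
    "result_to_json",
]

Mode = Literal["classification", "regression"]


class PredictorError(RuntimeError):
    """The user-supplied predictor violated its batch contract."""


@dataclass(frozen=True)
class PredictorContract:
    """The entire interface a model must expose: a batch function and a mode.

    ``predict`` maps a list of SMILES strings to a same-length list of
    outputs — labels for classification, finite reals for regression.
    """

    predict: Callable[[Sequence[str]], Sequence]
    mode: Mode

    def __post_init__(self) -> None:
        if self.mode not in ("classification", "regression"):
            raise ValueError(f"unknown mode: {self.mode!r}")

    def __call__(self, smiles: Sequence[str]) -> list:
        outputs = list(self.predict(list(smiles)))
        if len(outputs) != len(smiles):
            raise PredictorError(
                f"predictor returned {len(outputs)} outputs for "
                f"{len(smiles)} inputs"
            )
        if self.mode == "classification":
            for out in outputs:
                if isinstance(out, float) and not math.isfinite(out):
                    raise PredictorError("non-finite classification label")
        return outputs


@dataclass
class ExplanationCandidate:
    """A sampled molecule annotated with everything the selection needs."""

    record: MoleculeRecord
    similarity: float
    output: object
    is_counterfactual: bool
    cluster_id: int = -1
    direction: int = 0  # regression: +1 increase, -1 decrease, 0 n/a


@dataclass
class ExplanationResult:
    """Base molecule, chosen counterfactuals, and the full annotated space."""

    base: ExplanationCandidate
    counterfactuals: list[ExplanationCandidate]
    all_candidates: list[ExplanationCandidate]
    mode: Mode
    delta: float | None
    parameters: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)


def is_counterfactual(candidate_output, base_output, mode: Mode,
                      delta: float | None = None) -> tuple[bool, int]:
    """Apply the counterfactual condition; returns (flag, direction).

    direction is +1/-1 for a regression increase/decrease, else 0.
    """
    if mode == "classification":
        return candidate_output != base_output, 0
    if delta is None or not delta > 0:
        raise ValueError("regression mode requires delta > 0")
    change = float(candidate_output) - float(base_output)
    if abs(change) >= delta:
        return True, 1 if change > 0 else -1
    return False, 0


def cluster_candidates(candidates: Sequence[ExplanationCandidate],
                       eps: float = 0.15, min_samples: int = 5) -> np.ndarray:
    """DBSCAN labels over Tanimoto distances between the given candidates.

    Noise is labeled −1.  Fewer points than ``min_samples`` can still form a
    cluster only through density chaining; typically they all come out noise,
    which the selection stage handles.
    """
    if not 0 < eps < 1:
        raise ValueError("eps must be in (0, 1)")
    n = len(candidates)
    if n == 0:
        return np.empty(0, dtype=int)
    dmat = np.zeros((n, n))
    fps = [c.record.fingerprint for c in candidates]
    for i in range(n):
        for j in range(i + 1, n):
            dmat[i, j] = dmat[j, i] = distance(fps[i], fps[j])
    labels = DBSCAN(eps=eps, min_samples=min_samples,
                    metric="precomputed").fit_predict(dmat)
    return labels


def select_counterfactuals(candidates: Sequence[ExplanationCandidate],
                           labels: np.ndarray,
                           n_requested: int = 3) -> list[ExplanationCandidate]:
    """One representative per cluster, most-similar-first.

    Per non-noise cluster the member most similar to the base wins (ties
    break on lexicographically smallest canonical SMILES).  If that yields
    more than ``n_requested``, the most similar representatives are kept; if
    fewer, noise points top up the list by similarity.  The returned list is
    sorted by similarity, descending.
    """
    if n_requested < 1:
        raise ValueError("n_requested must be >= 1")

    def sort_key(c: ExplanationCandidate):
        return (-c.similarity, c.record.canonical_smiles)

    by_cluster: dict[int, list[ExplanationCandidate]] = {}
    noise: list[ExplanationCandidate] = []
    for cand, label in zip(candidates, labels):
        cand.cluster_id = int(label)
        if label == -1:
            noise.append(cand)
        else:
            by_cluster.setdefault(int(label), []).append(cand)

    representatives = [min(members, key=sort_key) for members in by_cluster.values()]
    representatives.sort(key=sort_key)
    chosen = representatives[:n_requested]
    if len(chosen) < n_requested:
        noise.sort(key=sort_key)
        chosen.extend(noise[: n_requested - len(chosen)])
    chosen.sort(key=sort_key)
    return chosen


def explain_space(base: MoleculeRecord,
                  candidates: Sequence[MoleculeRecord],
                  predictor: PredictorContract,
                  *,
                  eps: float = 0.15,
                  min_samples: int = 5,
                  n_requested: int = 3,
                  delta: float | None = None,
                  parameters: dict | None = None,
                  diagnostics: dict | None = None) -> ExplanationResult:
    """Run prediction, the counterfactual condition, clustering and selection
    over an already-enumerated candidate space (shared by both space sources).
    """
    smiles = [base.canonical_smiles] + [c.canonical_smiles for c in candidates]
    outputs = predictor(smiles)
    base_output = outputs[0]
    if predictor.mode == "regression" and not _finite(base_output):
        raise PredictorError("non-finite prediction for the base molecule")

    diag = dict(diagnostics or {})
    annotated: list[ExplanationCandidate] = []
    discarded = 0
    for rec, out in zip(candidates, outputs[1:]):
        if predictor.mode == "regression" and not _finite(out):
            discarded += 1
            continue
        flag, direction = is_counterfactual(out, base_output, predictor.mode, delta)
        annotated.append(ExplanationCandidate(
            record=rec,
            similarity=tanimoto(base.fingerprint, rec.fingerprint),
            output=out,
            is_counterfactual=flag,
            direction=direction,
        ))
    if discarded:
        diag["nonfinite_outputs_discarded"] = discarded

    cf_subset = [c for c in annotated if c.is_counterfactual]
    labels = cluster_candidates(cf_subset, eps=eps, min_samples=min_samples)
    chosen = select_counterfactuals(cf_subset, labels, n_requested)
    if not cf_subset:
        diag["advice"] = (
            "no candidate changed the prediction; consider a larger sample "
            "size or more mutations"
        )

    base_candidate = ExplanationCandidate(
        record=base, similarity=1.0, output=base_output,
        is_counterfactual=False, cluster_id=-1,
    )
    params = {
        "eps": eps,
        "min_samples": min_samples,
        "n_requested": n_requested,
        "delta": delta,
        "mode": predictor.mode,
        "canonicalizer": CANONICALIZER,
        "molcf_version": __version__,
    }
    params.update(parameters or {})
    return ExplanationResult(
        base=base_candidate,
        counterfactuals=chosen,
        all_candidates=annotated,
        mode=predictor.mode,
        delta=delta,
        parameters=params,
        diagnostics=diag,
    )


def explain(base_smiles: str,
            predictor: PredictorContract,
            sampler_config: SamplerConfig | None = None,
            *,
            eps: float = 0.15,
            min_samples: int = 5,
            n_requested: int = 3,
            delta: float | None = None) -> ExplanationResult:
    """End-to-end explanation: parse → enumerate → predict → select.

    Deterministic for a fixed sampler seed and a deterministic predictor.
    """
    if predictor.mode == "regression" and (delta is None or not delta > 0):
        raise ValueError("regression mode requires delta > 0")
    base = parse_molecule(base_smiles)
    config = sampler_config or SamplerConfig()
    candidates, sample_diag = expand_space(base, config)
    return explain_space(
        base, candidates, predictor,
        eps=eps, min_samples=min_samples, n_requested=n_requested, delta=delta,
        parameters={
            "num_samples": config.num_samples,
            "mutation_counts": sorted(config.mutation_counts),
            "alphabet": config.alphabet.name,
            "seed": config.seed,
        },
        diagnostics=dataclasses.asdict(sample_diag),
    )


def _finite(x) -> bool:
    try:
        return math.isfinite(float(x))
    except (TypeError, ValueError):
        return False


def project_space(candidates: Sequence[ExplanationCandidate]) -> np.ndarray:
    """Classical MDS of the candidate set into 2-D from Tanimoto distances.

    Eigen-decomposes the double-centered squared-distance matrix (principal
    coordinates); the two leading axes are returned, one row per candidate.
    Signs are fixed by making the largest-magnitude loading of each axis
    positive, so the projection is fully deterministic.
    """
    n = len(candidates)
    if n < 3:
        raise ValueError("projection needs at least 3 candidates")
    fps = [c.record.fingerprint for c in candidates]
    d2 = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d2[i, j] = d2[j, i] = distance(fps[i], fps[j]) ** 2
    j_mat = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j_mat @ d2 @ j_mat
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1][:2]
    coords = eigvec[:, order] * np.sqrt(np.clip(eigval[order], 0, None))
    for axis in range(coords.shape[1]):
        col = coords[:, axis]
        if col[np.argmax(np.abs(col))] < 0:
            coords[:, axis] = -col
    return coords


# ---------------------------------------------------------------------------
# result writers

_CSV_COLUMNS = ["canonical_smiles", "selfies", "similarity", "output",
                "is_counterfactual", "cluster_id"]


def _candidate_row(c: ExplanationCandidate) -> list:
    return [c.record.canonical_smiles, c.record.selfies,
            f"{c.similarity:.6f}", c.output, int(c.is_counterfactual),
            c.cluster_id]


def result_to_csv(result: ExplanationResult, which: str = "all") -> str:
    """Render the candidate table (``which='all'``) or the selected
    counterfactuals (``which='counterfactuals'``) as CSV text."""
    rows = {"all": result.all_candidates,
            "counterfactuals": result.counterfactuals}[which]
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(_CSV_COLUMNS)
    writer.writerow(_candidate_row(result.base))
    for cand in rows:
        writer.writerow(_candidate_row(cand))
    return buf.getvalue()


def _candidate_json(c: ExplanationCandidate) -> dict:
    return {
        "canonical_smiles": c.record.canonical_smiles,
        "input_smiles": c.record.input_smiles,
        "selfies": c.record.selfies,
        "similarity": c.similarity,
        "output": c.output,
        "is_counterfactual": c.is_counterfactual,
        "cluster_id": c.cluster_id,
        "direction": c.direction,
    }


def result_to_json(result: ExplanationResult) -> str:
    """Full :class:`ExplanationResult` as a JSON document."""
    doc = {
        "mode": result.mode,
        "delta": result.delta,
        "parameters": result.parameters,
        "diagnostics": result.diagnostics,
        "base": _candidate_json(result.base),
        "counterfactuals": [_candidate_json(c) for c in result.counterfactuals],
        "all_candidates": [_candidate_json(c) for c in result.all_candidates],
    }
    return json.dumps(doc, indent=2, sort_keys=True, default=str)
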
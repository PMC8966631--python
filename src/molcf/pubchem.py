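"""Chemical-space expansion from the PubChem database.

Instead of generating novel molecules by string mutation, the candidate space
can be populated with experimentally known compounds via PubChem's 2-D
similarity search (PUG-REST ``fastsimilarity_2d``).  The resulting molecules
tend to be less similar to the base than mutation-derived ones, but every one
of them exists.  Downstream — prediction, the counterfactual condition,
clustering, selection — is byte-for-byte the same pipeline; similarity to the
base is always recomputed locally with ECFP4/Tanimoto rather than trusted
from the service, so the two space sources share one metric.

Networking is injected: a transport is any callable ``url -> response text``.
Production uses a stdlib urllib transport with retry/backoff; tests use
canned fixture transports and never touch the network.  Responses are cached
on disk keyed by (query, threshold, max_records) so reruns are deterministic
and polite to the service.
"""

from __future__ import annotations

import hashlib
import json
import time
import urllib.error
import urllib.parse
import urllib.request
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

from rdkit import Chem

from .engine import ExplanationResult, PredictorContract, explain_space
from .molecules import InvalidSmilesError, MoleculeRecord, parse_molecule
from . import selfies as sf

__all__ = [
    "SimilarityQuery",
    "ServiceUnavailableError",
    "urllib_transport",
    "search_similar",
    "explain_from_database",
]

Transport = Callable[[str], str]

_PUG_REST = "https://pubchem.ncbi.nlm.nih.gov/rest/pug"


class ServiceUnavailableError(RuntimeError):
    """The similarity service could not be reached after retries."""


@dataclass(frozen=True)
class SimilarityQuery:
    """Parameters of one PubChem 2-D similarity search."""

    smiles: str
    threshold: int = 90       # Tanimoto percentage the service filters on
    max_records: int = 200
    timeout: float = 30.0

    def __post_init__(self) -> None:
        if not 0 < self.threshold <= 100:
            raise ValueError("threshold must be in (0, 100]")
        if self.max_records < 1:
            raise ValueError("max_records must be >= 1")

    def url(self) -> str:
        smiles = urllib.parse.quote(self.smiles, safe="")
        return (
            f"{_PUG_REST}/compound/fastsimilarity_2d/smiles/{smiles}/"
            f"property/CanonicalSMILES/JSON"
            f"?Threshold={self.threshold}&MaxRecords={self.max_records}"
        )


def urllib_transport(retries: int = 3, backoff: float = 2.0,
                     timeout: float = 30.0) -> Transport:
    """Default HTTP transport: stdlib urllib with exponential backoff."""

    def fetch(url: str) -> str:
        last: Exception | None = None
        for attempt in range(retries):
            try:
                with urllib.request.urlopen(url, timeout=timeout) as resp:
                    return resp.read().decode("utf-8")
            except (urllib.error.URLError, TimeoutError, OSError) as exc:
                last = exc
                if attempt < retries - 1:
                    time.sleep(backoff * (2 ** attempt))
        raise ServiceUnavailableError(f"similarity service unreachable: {last}")

    return fetch


def _cache_key(query: SimilarityQuery) -> str:
    raw = f"{query.smiles}|{query.threshold}|{query.max_records}"
    return hashlib.sha256(raw.encode()).hexdigest()[:32]


def _fetch(query: SimilarityQuery, transport: Transport,
           cache_dir: str | Path | None) -> dict:
    cache_path = None
    if cache_dir is not None:
        cache_path = Path(cache_dir) / f"pubchem-{_cache_key(query)}.json"
        if cache_path.exists():
            return json.loads(cache_path.read_text())
    text = transport(query.url())
    payload = json.loads(text)
    if cache_path is not None:
        cache_path.parent.mkdir(parents=True, exist_ok=True)
        cache_path.write_text(json.dumps(payload))
    return payload


def search_similar(query: SimilarityQuery, transport: Transport,
                   cache_dir: str | Path | None = None,
                   diagnostics: dict | None = None) -> list[MoleculeRecord]:
    """Similar known molecules, parsed and deduplicated, query excluded.

    Malformed records coming back from the service are skipped and counted in
    ``diagnostics`` (key ``skipped_records``), never raised.
    """
    payload = _fetch(query, transport, cache_dir)
    properties = (payload.get("PropertyTable") or {}).get("Properties") or []
    base = parse_molecule(query.smiles)
    seen = {base.canonical_smiles}
    records: list[MoleculeRecord] = []
    skipped = 0
    for prop in properties:
        smiles = prop.get("CanonicalSMILES") or prop.get("SMILES")
        if not smiles:
            skipped += 1
            continue
        try:
            rec = parse_molecule(smiles)
        except (InvalidSmilesError, sf.EncodingError):
            skipped += 1
            continue
        if rec.canonical_smiles in seen:
            continue
        seen.add(rec.canonical_smiles)
        records.append(rec)
    if diagnostics is not None:
        diagnostics["service_records"] = len(properties)
        diagnostics["skipped_records"] = skipped
    return records


def explain_from_database(base_smiles: str,
                          predictor: PredictorContract,
                          query: SimilarityQuery | None = None,
                          *,
                          transport: Transport | None = None,
                          cache_dir: str | Path | None = None,
                          eps: float = 0.15,
                          min_samples: int = 5,
                          n_requested: int = 3,
                          delta: float | None = None) -> ExplanationResult:
    """The full explanation pipeline with PubChem as the space source."""
    base = parse_molecule(base_smiles)
    if query is None:
        query = SimilarityQuery(smiles=base.canonical_smiles)
    if transport is None:
        transport = urllib_transport(timeout=query.timeout)
    diag: dict = {"source": "pubchem"}
    candidates = search_similar(query, transport, cache_dir, diagnostics=diag)
    if not candidates:
        diag["advice"] = (
            "similarity search returned no usable molecules; consider "
            "lowering the threshold or raising max_records"
        )
    return explain_space(
        base, candidates, predictor,
        eps=eps, min_samples=min_samples, n_requested=n_requested, delta=delta,
        parameters={
            "source": "pubchem",
            "threshold": query.threshold,
            "max_records": query.max_records,
        },
        diagnostics=diag,
    )
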
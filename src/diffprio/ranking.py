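"""Candidate-gene scoring and ranking.

Four scorers are provided.  The two *global* scorers compare a candidate
gene's whole diffusion profile with the disease's weighted diffusion
profile:

* ``dp_lcc`` -- Pearson linear correlation coefficient of the two profiles;
* ``dp_cos`` -- cosine of the angle between them.

The two *component* baselines read a single coordinate of a disease
stationary vector:

* ``rwr`` -- the candidate's component of the unweighted (lambda = 0)
  disease walk, the classical restart-walk prioritizer;
* ``prince`` -- PRINCE-style: the restart vector is a logistic transform
  ``L(x) = 1 / (1 + exp(c*x + d))`` of each gene's best phenotype similarity
  to the query disease (c = -15, d = log(9999)), and candidates are scored by
  their component of the resulting stationary vector.  Only the prior +
  walk + component reading is reproduced here, not the original method's
  edge-weight normalization or iterative refinement.

Ties are handled pessimistically: every member of a tie group receives the
worst (largest) rank of the group, so evaluation never credits an
uninformative scorer.  Scores that are undefined (a constant profile for the
correlation, an all-zero vector for the cosine) rank last.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from math import log
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .diffusion import (
    DEFAULT_GAMMA,
    DEFAULT_MAX_ITER,
    DEFAULT_TOL,
    GeneProfiles,
    indicator_distribution,
    rwr,
)
from .io import GeneNetwork, TransitionMatrix
from .phenotype import (
    DEFAULT_LAMBDA,
    DEFAULT_SIM_THRESHOLD,
    PhenotypeSimilarity,
    weighted_initial_distribution,
)

logger = logging.getLogger(__name__)

__all__ = [
    "METHODS",
    "UndefinedScoreError",
    "RankedResult",
    "lcc",
    "cosine",
    "score_rwr_baseline",
    "prince_prior",
    "rank_candidates",
    "rank_genome_wide",
    "PRINCE_C",
    "PRINCE_D",
]

METHODS = ("dp_lcc", "dp_cos", "rwr", "prince")

#: Logistic prior parameters of the PRINCE-style baseline.
PRINCE_C = -15.0
PRINCE_D = log(9999.0)


class UndefinedScoreError(ValueError):
    """A similarity score is undefined for the given profile pair."""


def lcc(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson linear correlation coefficient of two profile vectors.

    Raises :class:`UndefinedScoreError` if either vector is constant (zero
    variance), for which the correlation is undefined.
    """
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    if a.shape != b.shape or a.size < 2:
        raise ValueError("profiles must have equal length >= 2")
    ac = a - a.mean()
    bc = b - b.mean()
    denom = np.linalg.norm(ac) * np.linalg.norm(bc)
    if denom == 0:
        raise UndefinedScoreError("correlation undefined for a constant profile")
    return float(np.clip(ac @ bc / denom, -1.0, 1.0))


def cosine(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine of the angle between two profile vectors.

    Raises :class:`UndefinedScoreError` on an all-zero vector.
    """
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    if a.shape != b.shape:
        raise ValueError("profiles must have equal length")
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0:
        raise UndefinedScoreError("cosine undefined for a zero profile")
    return float(np.clip(a @ b / denom, -1.0, 1.0))


@dataclass(frozen=True)
class RankEntry:
    gene: str
    score: float
    rank: int


@dataclass
class RankedResult:
    """Candidate ranking for one disease under one scoring method."""

    disease: str
    method: str
    entries: list[RankEntry] = field(default_factory=list)

    def rank_of(self, gene: str) -> int:
        for entry in self.entries:
            if entry.gene == gene:
                return entry.rank
        raise KeyError(f"gene {gene!r} not among ranked candidates")

    def top(self, k: int) -> list[RankEntry]:
        return self.entries[:k]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "disease_id": self.disease,
                "gene_id": [e.gene for e in self.entries],
                "score": [e.score for e in self.entries],
                "rank": [e.rank for e in self.entries],
                "method": self.method,
            }
        )


def score_rwr_baseline(disease_profile: np.ndarray, gene: str,
                       transition: TransitionMatrix) -> float:
    """Component of the disease stationary vector at ``gene``."""
    if gene not in transition.node_index:
        raise KeyError(f"gene {gene!r} is not a network node")
    return float(np.asarray(disease_profile).ravel()[transition.node_index[gene]])


def prince_prior(disease: str,
                 associations: Mapping[str, Iterable[str]],
                 similarities: PhenotypeSimilarity,
                 network: GeneNetwork, *,
                 c: float = PRINCE_C, d: float = PRINCE_D) -> np.ndarray:
    """Logistic phenotype prior over all network genes, normalized to sum 1.

    For each gene ``g`` the prior is ``L(x_g)`` with ``x_g`` the largest
    similarity between ``disease`` and any disease caused by ``g`` (the
    disease's own genes get ``Sim = 1``); genes with no known disease take
    ``L(0)``, a small uniform floor.
    """
    best = np.zeros(network.n_nodes)
    for other in sorted(associations):
        sim = similarities.get(disease, other)
        if sim <= 0:
            continue
        for g in associations[other]:
            if g in network:
                i = network.node_index[g]
                if sim > best[i]:
                    best[i] = sim
    prior = 1.0 / (1.0 + np.exp(c * best + d))
    return prior / prior.sum()


def _disease_profile_for_method(disease: str, method: str, *,
                                transition: TransitionMatrix,
                                network: GeneNetwork,
                                associations: Mapping[str, Iterable[str]],
                                similarities: PhenotypeSimilarity | None,
                                gamma: float, lam: float, threshold: float,
                                tol: float, max_iter: int,
                                exclude_gene: str | None) -> np.ndarray:
    sims = similarities if similarities is not None else PhenotypeSimilarity()
    if method in ("dp_lcc", "dp_cos"):
        start = weighted_initial_distribution(
            disease, associations, sims, network,
            lam=lam, threshold=threshold, exclude_gene=exclude_gene,
        )
    elif method == "rwr":
        start = weighted_initial_distribution(
            disease, associations, sims, network, lam=0.0, threshold=threshold,
        )
    elif method == "prince":
        start = prince_prior(disease, associations, sims, network)
    else:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    return rwr(transition, start, gamma=gamma, tol=tol, max_iter=max_iter).values


def rank_candidates(disease: str, candidates: Sequence[str], method: str, *,
                    transition: TransitionMatrix,
                    network: GeneNetwork,
                    associations: Mapping[str, Iterable[str]],
                    similarities: PhenotypeSimilarity | None = None,
                    gene_profiles: GeneProfiles | None = None,
                    gamma: float = DEFAULT_GAMMA,
                    lam: float = DEFAULT_LAMBDA,
                    threshold: float = DEFAULT_SIM_THRESHOLD,
                    tol: float = DEFAULT_TOL,
                    max_iter: int = DEFAULT_MAX_ITER,
                    exclude_gene: str | None = None) -> RankedResult:
    """Score every candidate for ``disease`` and rank them descending.

    For the global methods each candidate's diffusion profile is taken from
    ``gene_profiles`` if supplied (they depend only on the network and gamma,
    so precomputing and reusing them across diseases is the intended use) and
    computed on the fly otherwise.  Ties receive the worst rank of their tie
    group; undefined scores are ranked last, with a warning.
    """
    candidates = list(dict.fromkeys(candidates))
    if not candidates:
        raise ValueError("empty candidate list")
    missing = [g for g in candidates if g not in network]
    if missing:
        raise KeyError(f"candidates not in network: {missing[:5]}")

    disease_profile = _disease_profile_for_method(
        disease, method, transition=transition, network=network,
        associations=associations, similarities=similarities,
        gamma=gamma, lam=lam, threshold=threshold, tol=tol,
        max_iter=max_iter, exclude_gene=exclude_gene,
    )

    scores = np.empty(len(candidates))
    if method in ("dp_lcc", "dp_cos"):
        measure = lcc if method == "dp_lcc" else cosine
        n_undefined = 0
        for i, gene in enumerate(candidates):
            if gene_profiles is not None:
                profile = gene_profiles.column(gene)
            else:
                profile = rwr(
                    transition, indicator_distribution(gene, network),
                    gamma=gamma, tol=tol, max_iter=max_iter,
                ).values
            try:
                scores[i] = measure(disease_profile, profile)
            except UndefinedScoreError:
                scores[i] = -np.inf
                n_undefined += 1
        if n_undefined:
            warnings.warn(
                f"{n_undefined} candidate(s) with undefined {method} score "
                "ranked last", RuntimeWarning, stacklevel=2,
            )
    else:
        idx = [transition.node_index[g] for g in candidates]
        scores = disease_profile[idx]

    ranks = rankdata(-scores, method="max").astype(int)
    order = sorted(range(len(candidates)),
                   key=lambda i: (ranks[i], candidates[i]))
    entries = [RankEntry(gene=candidates[i], score=float(scores[i]),
                         rank=int(ranks[i])) for i in order]
    return RankedResult(disease=disease, method=method, entries=entries)


def rank_genome_wide(disease: str, method: str = "dp_lcc", *,
                     transition: TransitionMatrix,
                     network: GeneNetwork,
                     associations: Mapping[str, Iterable[str]],
                     similarities: PhenotypeSimilarity | None = None,
                     gene_profiles: GeneProfiles | None = None,
                     top_k: int | None = None,
                     **kwargs) -> RankedResult:
    """Rank every network gene not already associated with ``disease``.

    ``top_k`` truncates the returned entry list after ranking (ranks are
    computed over the full candidate set first).
    """
    known = set(associations.get(disease, ()))
    candidates = [g for g in network.nodes if g not in known]
    if not candidates:
        raise ValueError(f"no candidate genes left for disease {disease!r}")
    result = rank_candidates(
        disease, candidates, method, transition=transition, network=network,
        associations=associations, similarities=similarities,
        gene_profiles=gene_profiles, **kwargs,
    )
    if top_k is not None:
        result.entries = result.entries[:top_k]
    return result
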
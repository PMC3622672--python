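"""Phenotype-similarity weighting of a disease's start distribution.

Diseases with similar phenotypes tend to be caused by functionally related
genes, so a disease's restart vector is enriched with the causal genes of
phenotypically similar diseases.  Given pairwise similarities ``Sim(d, di)``
in [0, 1] (MimMiner-style text-mining scores, consumed here as input), the
weighted start distribution of disease ``d`` is

    D~0 = D0 + lambda * sum_i [Sim(d, di) >= threshold] * Sim(d, di) * D0_i

where ``D0`` puts equal mass on d's own causal genes and ``D0_i`` on those of
disease ``di``.  Similarities below the informativeness threshold (default
0.3) are ignored.  The weighted vector is renormalized to total mass 1;
because the downstream correlation and cosine scores are invariant to
positive rescaling, this changes no ranking, only preserves the probabilistic
reading of the walk.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .diffusion import (
    DEFAULT_GAMMA,
    DEFAULT_MAX_ITER,
    DEFAULT_TOL,
    DiffusionProfile,
    disease_initial_distribution,
    rwr,
)
from .io import DataFormatError, GeneNetwork, TransitionMatrix, _data_lines

logger = logging.getLogger(__name__)

__all__ = [
    "PhenotypeSimilarity",
    "load_similarities",
    "write_similarities",
    "weighted_initial_distribution",
    "disease_diffusion_profile",
    "DEFAULT_LAMBDA",
    "DEFAULT_SIM_THRESHOLD",
]

#: Default weight of similar diseases' contributions; the grid search places
#: the best precision at lambda = 0.5.
DEFAULT_LAMBDA = 0.5
#: Similarities below this value carry no functional signal and are ignored.
DEFAULT_SIM_THRESHOLD = 0.3


class PhenotypeSimilarity:
    """Sparse symmetric pairwise similarity in [0, 1] between disease ids.

    The diagonal is not stored: ``get(d, d)`` returns 1.0 by convention
    (a phenotype is maximally similar to itself), and absent pairs return
    the supplied default (0.0).
    """

    def __init__(self, entries: Mapping[tuple[str, str], float] |
                 Iterable[tuple[str, str, float]] = ()) -> None:
        self._entries: dict[tuple[str, str], float] = {}
        self._by_disease: dict[str, dict[str, float]] = {}
        if isinstance(entries, Mapping):
            entries = ((a, b, v) for (a, b), v in entries.items())
        for a, b, value in entries:
            self.add(a, b, float(value))

    def add(self, a: str, b: str, value: float) -> None:
        if a == b:
            raise ValueError(f"diagonal entry for {a!r} is not storable")
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"similarity {value} outside [0, 1]")
        key = (a, b) if a < b else (b, a)
        existing = self._entries.get(key)
        if existing is not None and existing != value:
            raise ValueError(
                f"contradictory similarity for pair {key}: {existing} vs {value}"
            )
        self._entries[key] = value
        self._by_disease.setdefault(a, {})[b] = value
        self._by_disease.setdefault(b, {})[a] = value

    def get(self, a: str, b: str, default: float = 0.0) -> float:
        if a == b:
            return 1.0
        key = (a, b) if a < b else (b, a)
        return self._entries.get(key, default)

    def neighbors(self, disease: str, threshold: float = 0.0) -> list[tuple[str, float]]:
        """Diseases with stored similarity >= threshold, sorted by id."""
        near = self._by_disease.get(disease, {})
        return sorted((d, s) for d, s in near.items() if s >= threshold)

    def items(self) -> Iterable[tuple[tuple[str, str], float]]:
        return self._entries.items()

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        a, b = pair
        key = (a, b) if a < b else (b, a)
        return key in self._entries


def load_similarities(path: str | Path) -> PhenotypeSimilarity:
    """Load a 3-column TSV (disease_a, disease_b, similarity).

    Entries are symmetrized; a pair stated twice with conflicting values, a
    value outside [0, 1], or a malformed line raises :class:`DataFormatError`
    with the line number.  Diagonal lines are skipped with a logged count.
    """
    sims = PhenotypeSimilarity()
    n_diag = 0
    for lineno, fields in _data_lines(path):
        if len(fields) < 3:
            raise DataFormatError(
                f"{path}:{lineno}: expected 3 fields "
                f"(disease_a, disease_b, similarity), got {len(fields)}"
            )
        a, b = fields[0], fields[1]
        try:
            value = float(fields[2])
        except ValueError as exc:
            raise DataFormatError(f"{path}:{lineno}: non-numeric similarity") from exc
        if a == b:
            n_diag += 1
            continue
        try:
            sims.add(a, b, value)
        except ValueError as exc:
            raise DataFormatError(f"{path}:{lineno}: {exc}") from exc
    if n_diag:
        logger.info("skipped %d diagonal similarity entries", n_diag)
    return sims


def write_similarities(sims: PhenotypeSimilarity, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("# disease_a\tdisease_b\tsimilarity\n")
        for (a, b), value in sorted(sims.items()):
            handle.write(f"{a}\t{b}\t{value:.17g}\n")


def weighted_initial_distribution(disease: str,
                                  associations: Mapping[str, Iterable[str]],
                                  similarities: PhenotypeSimilarity,
                                  network: GeneNetwork, *,
                                  lam: float = DEFAULT_LAMBDA,
                                  threshold: float = DEFAULT_SIM_THRESHOLD,
                                  exclude_gene: str | None = None) -> np.ndarray:
    """Similarity-weighted start distribution of ``disease``.

    With ``lam == 0``, or when no other disease reaches the similarity
    threshold, the unweighted equal-mass vector is returned unchanged (bit
    for bit).  Otherwise contributions are accumulated in sorted disease-id
    order and the result renormalized to sum 1.  The disease itself never
    contributes through the similarity sum.

    ``exclude_gene`` removes one gene from every *contributing* disease's
    distribution (not from ``disease``'s own); leave-one-out evaluation uses
    this for strict holdout, where the held-out gene must not re-enter
    through a similar disease.
    """
    if lam < 0:
        raise ValueError(f"lambda must be nonnegative, got {lam}")
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    d0 = disease_initial_distribution(disease, associations, network)
    if lam == 0:
        return d0
    acc = np.zeros_like(d0)
    contributed = False
    for other, sim in similarities.neighbors(disease, threshold):
        if other == disease or other not in associations:
            continue
        genes = sorted(
            g for g in associations[other]
            if g in network and g != exclude_gene
        )
        if not genes:
            logger.debug(
                "similar disease %s contributes no in-network genes to %s",
                other, disease,
            )
            continue
        d0i = np.zeros_like(d0)
        for g in genes:
            d0i[network.node_index[g]] = 1.0 / len(genes)
        acc += lam * sim * d0i
        contributed = True
    if not contributed:
        return d0
    weighted = d0 + acc
    return weighted / weighted.sum()


def disease_diffusion_profile(disease: str,
                              associations: Mapping[str, Iterable[str]],
                              similarities: PhenotypeSimilarity,
                              transition: TransitionMatrix,
                              network: GeneNetwork, *,
                              gamma: float = DEFAULT_GAMMA,
                              lam: float = DEFAULT_LAMBDA,
                              threshold: float = DEFAULT_SIM_THRESHOLD,
                              tol: float = DEFAULT_TOL,
                              max_iter: int = DEFAULT_MAX_ITER,
                              exclude_gene: str | None = None) -> DiffusionProfile:
    """Stationary distribution of the walk started from the weighted vector.

    With ``lam == 0`` this is the plain disease walk from the equal-mass
    causal-gene vector.
    """
    d0 = weighted_initial_distribution(
        disease, associations, similarities, network,
        lam=lam, threshold=threshold, exclude_gene=exclude_gene,
    )
    return rwr(transition, d0, gamma=gamma, tol=tol, max_iter=max_iter)
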
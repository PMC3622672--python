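"""Leave-one-out cross-validation and evaluation metrics.

Each known disease--gene association is held out in turn; the method
rebuilds the disease's (weighted) diffusion profile from the remaining
associations and ranks the held-out gene against a control set of
``n_controls`` genes (default 99, giving candidate sets of 100).  Controls
are either drawn uniformly at random from the interactome or taken as the
genes genomically nearest to the held-out gene (an artificial linkage
interval, mimicking a mapped chromosomal candidate region).

Reported metrics:

* **PRE** -- the count and proportion of cases in which the held-out gene
  outranks every control (rank 1);
* **rank-ratio ROC / AUC** -- the rank ratio is ``rank / candidate-set
  size``; sweeping a threshold over the 0.01 grid, sensitivity is the
  fraction of held-out genes at or below the threshold and specificity the
  fraction of control genes above it; AUC by the trapezoidal rule;
* **PR curve** -- precision/recall over the pooled candidate scores, with
  held-out genes as positives.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .diffusion import (
    DEFAULT_GAMMA,
    DEFAULT_MAX_ITER,
    DEFAULT_TOL,
    GeneProfiles,
    all_gene_profiles,
)
from .io import GeneNetwork, GenePositions, TransitionMatrix, build_transition_matrix
from .phenotype import DEFAULT_LAMBDA, DEFAULT_SIM_THRESHOLD, PhenotypeSimilarity
from .ranking import METHODS, rank_candidates

logger = logging.getLogger(__name__)

__all__ = [
    "CVConfig",
    "CVCase",
    "CVResult",
    "select_controls_random",
    "select_controls_ali",
    "run_loocv",
    "roc_from_rank_ratios",
    "pr_curve",
    "parameter_sweep",
]

# tolerance for float threshold comparisons on the rank-ratio grid
_GRID_EPS = 1e-12


@dataclass(frozen=True)
class CVConfig:
    """Parameters of one cross-validation run."""

    method: str = "dp_lcc"
    control_mode: str = "random"  # "random" | "ali"
    n_controls: int = 99
    gamma: float = DEFAULT_GAMMA
    lam: float = DEFAULT_LAMBDA
    sim_threshold: float = DEFAULT_SIM_THRESHOLD
    tol: float = DEFAULT_TOL
    max_iter: int = DEFAULT_MAX_ITER
    rank_ratio_step: float = 0.01
    seed: int = 0
    #: remove the held-out gene from similar diseases' start vectors too
    strict_holdout: bool = False
    #: keep the disease's other (training) genes out of random control draws
    exclude_cocausal_controls: bool = True

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if self.control_mode not in ("random", "ali"):
            raise ValueError(f"unknown control mode {self.control_mode!r}")
        if self.n_controls < 1:
            raise ValueError("n_controls must be >= 1")
        if not 0 < self.rank_ratio_step <= 1:
            raise ValueError("rank_ratio_step must be in (0, 1]")


@dataclass(frozen=True)
class CVCase:
    """One leave-one-out round."""

    disease: str
    gene: str
    rank: int
    n_candidates: int
    rank_ratio: float
    control_rank_ratios: np.ndarray


@dataclass
class CVResult:
    """Aggregated leave-one-out results."""

    cases: list[CVCase]
    pre_count: int
    pre_proportion: float
    roc: pd.DataFrame
    auc: float
    pr: pd.DataFrame
    n_skipped: int = 0
    config: CVConfig | None = None

    @property
    def n_cases(self) -> int:
        return len(self.cases)

    def cases_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "disease_id": [c.disease for c in self.cases],
                "gene_id": [c.gene for c in self.cases],
                "rank": [c.rank for c in self.cases],
                "n_candidates": [c.n_candidates for c in self.cases],
                "rank_ratio": [c.rank_ratio for c in self.cases],
            }
        )

    def summary(self) -> dict:
        return {
            "n_cases": self.n_cases,
            "n_skipped": self.n_skipped,
            "pre_count": self.pre_count,
            "pre_proportion": self.pre_proportion,
            "auc": self.auc,
        }


def select_controls_random(test_gene: str, network: GeneNetwork, n: int,
                           rng: np.random.Generator, *,
                           exclude: Iterable[str] = ()) -> frozenset[str]:
    """Uniform sample of ``n`` control genes, never including the test gene.

    ``exclude`` removes further genes from the eligible pool (the LOOCV
    driver passes the disease's training genes so a control cannot itself be
    a known causal gene of the query disease).
    """
    banned = {test_gene} | set(exclude)
    pool = [g for g in network.nodes if g not in banned]
    if len(pool) < n:
        raise ValueError(
            f"cannot draw {n} controls from {len(pool)} eligible genes"
        )
    picked = rng.choice(len(pool), size=n, replace=False)
    return frozenset(pool[i] for i in picked)


def select_controls_ali(test_gene: str, positions: GenePositions,
                        network: GeneNetwork, n: int,
                        rng: np.random.Generator | None = None, *,
                        exclude: Iterable[str] = ()) -> frozenset[str]:
    """Artificial linkage interval: the ``n`` genes nearest the test gene.

    Distance is absolute midpoint distance on the test gene's chromosome;
    ties break by gene id.  If the chromosome holds fewer than ``n`` eligible
    genes the remaining slots are filled by a random draw from the rest of
    the network (logged) -- with no generator supplied, by the
    lexicographically first remaining genes.
    """
    if test_gene not in positions:
        raise KeyError(f"test gene {test_gene!r} has no position record")
    chrom, mid = positions.midpoint(test_gene)
    banned = {test_gene} | set(exclude)
    scored: list[tuple[float, str]] = []
    for gene in network.nodes:
        if gene in banned or gene not in positions:
            continue
        other_chrom, other_mid = positions.midpoint(gene)
        if other_chrom != chrom:
            continue
        scored.append((abs(other_mid - mid), gene))
    scored.sort()
    controls = {gene for _, gene in scored[:n]}
    if len(controls) < n:
        need = n - len(controls)
        pool = sorted(
            g for g in network.nodes
            if g not in controls and g not in banned
        )
        if len(pool) < need:
            raise ValueError(
                f"cannot assemble {n} controls for {test_gene!r}"
            )
        logger.info(
            "chromosome %s holds only %d eligible genes; filling %d control "
            "slots at random", chrom, len(controls), need,
        )
        if rng is None:
            fill = pool[:need]
        else:
            fill = [pool[i] for i in rng.choice(len(pool), size=need,
                                                replace=False)]
        controls.update(fill)
    return frozenset(controls)


def roc_from_rank_ratios(test_rank_ratios: Sequence[float],
                         control_rank_ratios: Sequence[float],
                         step: float = 0.01) -> tuple[pd.DataFrame, float]:
    """ROC over a rank-ratio threshold grid, plus trapezoidal AUC.

    At each threshold t in {0, step, 2*step, ..., 1}: sensitivity is the
    fraction of held-out genes with rank ratio <= t, specificity the
    fraction of control genes with rank ratio > t.  The curve includes the
    (0, 0) and (1, 1) endpoints.
    """
    test_rr = np.asarray(test_rank_ratios, dtype=np.float64)
    control_rr = np.asarray(control_rank_ratios, dtype=np.float64)
    if test_rr.size == 0:
        raise ValueError("no cases to evaluate")
    n_steps = int(round(1.0 / step))
    thresholds = np.arange(n_steps + 1) * step
    sens = np.array([(test_rr <= t + _GRID_EPS).mean() for t in thresholds])
    if control_rr.size:
        spec = np.array([(control_rr > t + _GRID_EPS).mean() for t in thresholds])
    else:
        spec = np.zeros_like(thresholds)
    frame = pd.DataFrame(
        {"threshold": thresholds, "sensitivity": sens, "specificity": spec}
    )
    x = np.concatenate(([0.0], 1.0 - spec, [1.0]))
    y = np.concatenate(([0.0], sens, [1.0]))
    order = np.lexsort((y, x))
    auc = float(np.trapezoid(y[order], x[order]))
    return frame, auc


def pr_curve(scores: Sequence[float], labels: Sequence[int]) -> pd.DataFrame:
    """Precision--recall curve by sweeping the observed score values.

    ``labels`` are 1 for true (held-out) disease genes, 0 for controls.  At
    each threshold, positive calls are the candidates scoring at or above
    it; precision is the fraction of calls that are disease genes and recall
    the fraction of disease genes called.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one positive and one negative")
    rows = []
    for t in np.unique(scores)[::-1]:
        called = scores >= t
        n_called = int(called.sum())
        tp = int(labels[called].sum())
        rows.append(
            {
                "threshold": float(t),
                "precision": tp / n_called,
                "recall": tp / n_pos,
            }
        )
    return pd.DataFrame(rows)


def _loocv_cases(associations: Mapping[str, Iterable[str]],
                 network: GeneNetwork) -> list[tuple[str, str]]:
    """All (disease, gene) pairs eligible for holdout: diseases keeping at
    least one in-network training gene after removal."""
    cases = []
    for disease in sorted(associations):
        genes = sorted(g for g in associations[disease] if g in network)
        if len(genes) < 2:
            continue
        cases.extend((disease, g) for g in genes)
    return cases


def run_loocv(associations: Mapping[str, Iterable[str]],
              similarities: PhenotypeSimilarity | None,
              network: GeneNetwork,
              config: CVConfig, *,
              positions: GenePositions | None = None,
              transition: TransitionMatrix | None = None,
              gene_profiles: GeneProfiles | None = None) -> CVResult:
    """Leave-one-out cross-validation of one method under one configuration.

    For every eligible association (d, g): g is removed from d's gene set,
    d's profile is rebuilt from the remaining training data, and g is ranked
    against its control set (candidate set size ``n_controls + 1``).
    Control draws are derived deterministically from ``config.seed`` and the
    case index, so results are reproducible and independent of evaluation
    order.  Gene profiles for the global methods are precomputed once per
    run when not supplied.
    """
    if transition is None:
        transition = build_transition_matrix(network)
    cases_todo = _loocv_cases(associations, network)
    if not cases_todo:
        raise ValueError("no evaluable leave-one-out cases "
                         "(every disease needs >= 2 in-network genes)")
    if config.control_mode == "ali" and positions is None:
        raise ValueError("ALI control mode requires gene positions")
    if config.method in ("dp_lcc", "dp_cos") and gene_profiles is None:
        logger.info("precomputing %d gene profiles (gamma=%g)",
                    network.n_nodes, config.gamma)
        gene_profiles = all_gene_profiles(
            transition, gamma=config.gamma, tol=config.tol,
            max_iter=config.max_iter,
        )

    cases: list[CVCase] = []
    pooled_scores: list[float] = []
    pooled_labels: list[int] = []
    n_skipped = 0
    for index, (disease, gene) in enumerate(cases_todo):
        rng = np.random.default_rng([config.seed, index])
        training = dict(associations)
        training[disease] = frozenset(set(associations[disease]) - {gene})
        cocausal = set(training[disease]) if config.exclude_cocausal_controls else set()
        try:
            if config.control_mode == "random":
                controls = select_controls_random(
                    gene, network, config.n_controls, rng, exclude=cocausal,
                )
            else:
                controls = select_controls_ali(
                    gene, positions, network, config.n_controls, rng,
                    exclude=cocausal,
                )
        except KeyError as exc:
            logger.warning("skipping case (%s, %s): %s", disease, gene, exc)
            n_skipped += 1
            continue
        candidates = sorted({gene} | controls)
        result = rank_candidates(
            disease, candidates, config.method,
            transition=transition, network=network, associations=training,
            similarities=similarities, gene_profiles=gene_profiles,
            gamma=config.gamma, lam=config.lam,
            threshold=config.sim_threshold, tol=config.tol,
            max_iter=config.max_iter,
            exclude_gene=gene if config.strict_holdout else None,
        )
        m = len(candidates)
        rank = result.rank_of(gene)
        control_rr = np.array(
            sorted(e.rank / m for e in result.entries if e.gene != gene)
        )
        cases.append(CVCase(disease=disease, gene=gene, rank=rank,
                            n_candidates=m, rank_ratio=rank / m,
                            control_rank_ratios=control_rr))
        for entry in result.entries:
            pooled_scores.append(entry.score)
            pooled_labels.append(1 if entry.gene == gene else 0)
    if not cases:
        raise ValueError("all leave-one-out cases were skipped")

    pre_count = sum(1 for c in cases if c.rank == 1)
    roc, auc = roc_from_rank_ratios(
        [c.rank_ratio for c in cases],
        np.concatenate([c.control_rank_ratios for c in cases]),
        step=config.rank_ratio_step,
    )
    finite = np.isfinite(pooled_scores)
    pr = pr_curve(
        np.where(finite, pooled_scores, np.min(np.asarray(pooled_scores)[finite],
                                               initial=0.0) - 1.0),
        pooled_labels,
    )
    return CVResult(cases=cases, pre_count=pre_count,
                    pre_proportion=pre_count / len(cases), roc=roc, auc=auc,
                    pr=pr, n_skipped=n_skipped, config=config)


def parameter_sweep(associations: Mapping[str, Iterable[str]],
                    similarities: PhenotypeSimilarity | None,
                    network: GeneNetwork, *,
                    gammas: Sequence[float],
                    lams: Sequence[float],
                    methods: Sequence[str] = METHODS,
                    base_config: CVConfig = CVConfig(),
                    positions: GenePositions | None = None) -> pd.DataFrame:
    """Grid evaluation over gamma and lambda for each method.

    Emits one row per (method, gamma, lambda) with PRE (count and
    proportion) and AUC.  Gene profiles are computed once per gamma and
    shared across lambdas and the two global methods.
    """
    transition = build_transition_matrix(network)
    rows = []
    for gamma in gammas:
        profiles: GeneProfiles | None = None
        if any(m in ("dp_lcc", "dp_cos") for m in methods):
            profiles = all_gene_profiles(
                transition, gamma=gamma, tol=base_config.tol,
                max_iter=base_config.max_iter,
            )
        for lam in lams:
            for method in methods:
                config = replace(base_config, method=method, gamma=gamma,
                                 lam=lam)
                result = run_loocv(
                    associations, similarities, network, config,
                    positions=positions, transition=transition,
                    gene_profiles=profiles,
                )
                rows.append(
                    {
                        "method": method,
                        "gamma": gamma,
                        "lambda": lam,
                        "n_cases": result.n_cases,
                        "pre_count": result.pre_count,
                        "pre_proportion": result.pre_proportion,
                        "auc": result.auc,
                    }
                )
    return pd.DataFrame(rows)
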
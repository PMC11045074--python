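"""Monte-Carlo calibration of LOD-score cut-offs.

Genotype pairs are simulated from the fitted allele frequencies for each
kinship category (per locus: draw the IBD state from the category's
Cotterman coefficients, build true genotypes under Hardy–Weinberg and
Mendelian transmission, pass them through the genotyping-error channel),
then scored with the same model context used for the real data.  The
resulting LOD distributions give, for any cut-off ``c``:

* false-positive rate — fraction of simulated unrelated pairs with
  scored LOD > c *and* maximum-likelihood category equal to the target;
* false-negative rate — fraction of simulated true-category pairs that
  fail that joint criterion.

Expected false-positive counts scale the per-pair rate by the total number
of pairs compared (almost all of which are unrelated).  The expected
false-negative count scales the rate by the *true* kin count, which is
itself unknown; ``corrected_count_fixed_point`` resolves the circularity.
Per-pair rates below Monte-Carlo resolution (no exceedances among n
replicates) are reported as "< 1/n", never extrapolated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .kinship_model import (HYPOTHESES, ML_PRIORITY, KinshipModelContext,
                            PairScore, _as_hypothesis)

logger = logging.getLogger(__name__)

__all__ = [
    "LODDistribution",
    "PairSimulation",
    "CutoffTable",
    "simulate_pairs",
    "error_rates",
    "build_cutoff_table",
    "corrected_kin_count",
    "corrected_count_fixed_point",
]


@dataclass(frozen=True)
class LODDistribution:
    """Simulated LOD values for one (scored hypothesis, generating category)."""

    scored_hypothesis: str
    category: str
    samples: np.ndarray
    n: int
    seed: int

    def __post_init__(self):
        if self.samples.size != self.n:
            raise ValueError("sample count does not match n")

    def quantile(self, q) -> float:
        return float(np.quantile(self.samples, q))


@dataclass(frozen=True)
class PairSimulation:
    """A batch of simulated genotype pairs scored under several hypotheses."""

    category: str
    n: int
    seed: int
    lods: Mapping[str, np.ndarray]   # hypothesis label -> (n,) LOD values
    ml: np.ndarray                   # maximum-likelihood category per pair
    genotypes: tuple | None = None   # optional ((n, L), (n, L)) genotype codes

    def distribution(self, scored_hypothesis: str) -> LODDistribution:
        return LODDistribution(scored_hypothesis, self.category,
                               self.lods[scored_hypothesis], self.n, self.seed)


def _draw_alleles(rng: np.random.Generator, freqs: np.ndarray, size: int) -> np.ndarray:
    return rng.choice(len(freqs), size=size, p=freqs)


def _apply_error(rng, alleles: np.ndarray, freqs: np.ndarray, error) -> np.ndarray:
    eps = error.epsilon
    if eps == 0.0 or len(freqs) == 1:
        return alleles
    out = alleles.copy()
    hit = rng.random(alleles.size) < eps
    n_hit = int(hit.sum())
    if n_hit:
        if error.mode == "freq_draw":
            out[hit] = _draw_alleles(rng, freqs, n_hit)
        else:  # uniform over the other k-1 alleles
            k = len(freqs)
            out[hit] = (out[hit] + rng.integers(1, k, size=n_hit)) % k
    return out


def simulate_pairs(ctx: KinshipModelContext, category, n: int, seed: int,
                   scored: Sequence[str] = ("PO", "FS", "HS"),
                   return_genotypes: bool = False) -> PairSimulation:
    """Simulate ``n`` genotype pairs of one kinship category and score them.

    Loci are unlinked: the IBD state is drawn independently per locus from
    the category's kappa vector.  Reproducible given ``seed``.  With
    ``return_genotypes`` the observed genotype codes of both pair members
    are kept (one (n, n_loci) array each).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    cat = _as_hypothesis(category)
    kappa = np.asarray(cat.kappa)
    rng = np.random.default_rng(seed)
    labels = tuple(dict.fromkeys(tuple(scored) + ("U",)))
    for label in labels:
        if label not in ctx.hypothesis_labels:
            raise ValueError(f"hypothesis {label} not cached in context")

    lod_sums = {label: np.zeros(n) for label in labels if label != "U"}
    geno1 = np.empty((n, len(ctx.tables)), dtype=np.int32) if return_genotypes else None
    geno2 = np.empty((n, len(ctx.tables)), dtype=np.int32) if return_genotypes else None
    for pos, tab in enumerate(ctx.tables):
        p = tab.locus.freqs
        a1, a2 = _draw_alleles(rng, p, n), _draw_alleles(rng, p, n)
        b1, b2 = _draw_alleles(rng, p, n), _draw_alleles(rng, p, n)
        ibd = rng.choice(3, size=n, p=kappa)
        one = ibd == 1
        if one.any():
            pick_first = rng.random(n) < 0.5
            b1[one] = np.where(pick_first[one], a1[one], a2[one])
        two = ibd == 2
        if two.any():
            b1[two], b2[two] = a1[two], a2[two]

        o = [_apply_error(rng, x, p, ctx.error) for x in (a1, a2, b1, b2)]
        g1 = tab.geno_index[o[0], o[1]]
        g2 = tab.geno_index[o[2], o[3]]
        if return_genotypes:
            geno1[:, pos], geno2[:, pos] = g1, g2
        for label in lod_sums:
            lod_sums[label] += tab.logratio[label][g1, g2]

    lods = dict(lod_sums)
    lods["U"] = np.zeros(n)
    order = [l for l in ML_PRIORITY if l in lods]
    stacked = np.vstack([np.where(np.isnan(lods[l]), -np.inf, lods[l]) for l in order])
    pick = np.argmax(stacked == stacked.max(axis=0)[None, :], axis=0)
    ml = np.array(order, dtype=object)[pick]
    genotypes = (geno1, geno2) if return_genotypes else None
    return PairSimulation(cat.label, n, seed, lods, ml, genotypes)


def _joint_pass(sim: PairSimulation, scored_hyp: str, category: str,
                cutoff: float) -> np.ndarray:
    return (sim.lods[scored_hyp] > cutoff) & (sim.ml == category)


def error_rates(sim_unrelated: PairSimulation, cutoff_grid: Sequence[float],
                scored_hyp: str = "PO", target_category: str = "PO",
                sim_true: PairSimulation | None = None) -> pd.DataFrame:
    """Per-cutoff false-positive and false-negative rates.

    FP rate: simulated unrelated pairs passing the joint criterion (scored
    LOD above the cutoff *and* classified as the target category).  FN
    rate: simulated true-category pairs failing it (requires ``sim_true``).
    Zero-exceedance FP rates carry an ``fp_upper`` resolution bound of 1/n.
    """
    cutoffs = list(cutoff_grid)
    if not cutoffs:
        raise ValueError("empty cutoff grid")
    if sim_unrelated.category != "U":
        raise ValueError("sim_unrelated must be generated under U")
    rows = []
    for c in cutoffs:
        fp = float(_joint_pass(sim_unrelated, scored_hyp, target_category, c).mean())
        row = {
            "scored_hyp": scored_hyp,
            "category": target_category,
            "cutoff": float(c),
            "fp_rate": fp,
            "fp_upper": 1.0 / sim_unrelated.n if fp == 0.0 else np.nan,
        }
        if sim_true is not None:
            row["fn_rate"] = float(
                1.0 - _joint_pass(sim_true, scored_hyp, target_category, c).mean())
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class CutoffTable:
    """Observed kin counts with expected false positives/negatives per cutoff.

    One row per (scored hypothesis, cutoff, category): the number of data
    pairs passing the joint criterion, the expected number of unrelated
    pairs doing so by chance, and — for the PO category — the expected
    number of true pairs missed plus the corrected count.
    """

    frame: pd.DataFrame
    n_pairs_total: int

    def row(self, scored_hyp: str, cutoff: float, category: str) -> pd.Series:
        f = self.frame
        m = ((f.scored_hyp == scored_hyp) & (f.cutoff == cutoff)
             & (f.category == category))
        return f[m].iloc[0]


def build_cutoff_table(pairscores: Sequence[PairScore],
                       sims: Mapping[str, PairSimulation],
                       cutoffs: Sequence[float],
                       scored_hyps: Sequence[str] = ("HS", "PO"),
                       categories: Sequence[str] = ("FS", "HS", "PO")) -> CutoffTable:
    """Cross-tabulate data pairs against cutoffs with FP/FN expectations.

    ``sims`` must contain a ``"U"`` simulation; an entry for a category
    (e.g. ``"PO"``) enables its FN accounting.  Expected FP counts scale
    the simulated rate by the total number of data pairs.
    """
    cutoffs = sorted(float(c) for c in cutoffs)
    if not cutoffs:
        raise ValueError("empty cutoff grid")
    if "U" not in sims:
        raise ValueError("sims must include an unrelated ('U') simulation")
    n_total = len(pairscores)

    rows = []
    for scored in scored_hyps:
        data_lod = np.array([s.lod[scored] for s in pairscores])
        data_ml = np.array([s.ml_category for s in pairscores], dtype=object)
        for c in cutoffs:
            for cat in categories:
                observed = int(((data_lod > c) & (data_ml == cat)).sum())
                fp_rate = float(_joint_pass(sims["U"], scored, cat, c).mean())
                expected_fp = fp_rate * n_total
                row = {
                    "scored_hyp": scored, "cutoff": c, "category": cat,
                    "observed": observed, "fp_rate": fp_rate,
                    "expected_fp": expected_fp,
                    "fp_below_resolution": fp_rate == 0.0,
                    "fn_rate": np.nan, "expected_fn": np.nan, "corrected": np.nan,
                }
                if cat in sims:
                    fn_rate = float(1.0 - _joint_pass(sims[cat], scored, cat, c).mean())
                    corrected, expected_fn = corrected_count_fixed_point(
                        observed, expected_fp, fn_rate)
                    row.update(fn_rate=fn_rate, expected_fn=expected_fn,
                               corrected=corrected)
                rows.append(row)
    return CutoffTable(pd.DataFrame(rows), n_total)


def corrected_kin_count(observed: float, expected_fp: float, expected_fn: float) -> float:
    """Unbiased kin count: observed − expected FP + expected FN."""
    if min(observed, expected_fp, expected_fn) < 0:
        raise ValueError("inputs must be non-negative")
    out = observed - expected_fp + expected_fn
    if out < 0:
        logger.warning("corrected kin count is negative (%.3f)", out)
    return float(out)


def corrected_count_fixed_point(observed: float, expected_fp: float, fn_rate: float,
                                tol: float = 1e-6, max_iter: int = 10000):
    """Corrected count when the FN expectation scales with the (unknown) truth.

    Solves ``N = observed − expected_fp + fn_rate · N`` by iteration to
    relative tolerance ``tol``; returns ``(N, expected_fn)``.
    """
    if not 0.0 <= fn_rate < 1.0:
        raise ValueError(f"fn_rate {fn_rate} outside [0, 1)")
    n = max(observed - expected_fp, 0.0)
    for _ in range(max_iter):
        new = observed - expected_fp + fn_rate * n
        if abs(new - n) <= tol * max(abs(new), 1.0):
            n = new
            break
        n = new
    if n < 0:
        logger.warning("corrected kin count is negative (%.3f)", n)
    return float(n), float(fn_rate * n)
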
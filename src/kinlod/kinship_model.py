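"""Pairwise kinship likelihoods and LOD scores for microsatellite genotypes.

The probability that two individuals show genotypes :math:`G_i, G_j` under a
kinship hypothesis is built from the Cotterman (identity-by-descent)
coefficients :math:`(\\kappa_0, \\kappa_1, \\kappa_2)` — the probabilities
that the pair shares 0, 1 or 2 alleles IBD at a locus::

    P(g1, g2 | K) = k0 P(g1)P(g2) + k1 P(g1) T(g2|g1) + k2 P(g1) [g1 = g2]

with ``P`` the Hardy–Weinberg genotype probability and ``T`` the Mendelian
parent–offspring transition.  Unrelated U = (1,0,0), parent–offspring
PO = (0,1,0), full siblings FS = (1/4,1/2,1/4), half siblings
HS = (1/2,1/2,0) (shared with grandparent–grandchild and avuncular pairs,
which are indistinguishable from pairwise genotypes), and self/monozygotic
SELF = (0,0,1).

Observed genotypes may contain typing errors.  A constant, independent
per-allele error rate ``epsilon`` maps true to observed genotypes; summing
the true-genotype-pair probability over this channel keeps every observed
pair's probability strictly positive, so the LOD score

    LOD_K(i, j) = ln P(G_i, G_j | K) − ln P(G_i, G_j | U)

is finite for all pairs (without the error model a single incompatible
locus makes LOD_PO = −inf).  LODs are summed over the loci typed in both
individuals.  Per-locus probability tables are cached in
:class:`KinshipModelContext`, so scoring a pair is a table lookup per locus.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .genotype_io import Genotype, LocusModel, SampleRecord, _canonical_call

logger = logging.getLogger(__name__)

__all__ = [
    "KinshipHypothesis",
    "ErrorModel",
    "KinshipModelContext",
    "PairScore",
    "HYPOTHESES",
    "ML_PRIORITY",
    "hwe_genotype_prob",
    "po_transition_prob",
    "true_pair_prob",
    "observed_pair_prob",
    "lod",
    "score_all_pairs",
    "pairs_to_frame",
    "encode_genotypes",
    "pairwise_lod",
    "ml_category",
]


@dataclass(frozen=True)
class KinshipHypothesis:
    """A named relationship with its IBD coefficient vector."""

    label: str
    kappa: tuple
    notes: str = ""

    def __post_init__(self):
        k = tuple(float(x) for x in self.kappa)
        if len(k) != 3 or abs(sum(k) - 1.0) > 1e-12 or any(x < 0 for x in k):
            raise ValueError(f"{self.label}: invalid kappa {self.kappa}")
        object.__setattr__(self, "kappa", k)


HYPOTHESES: dict = {
    "U": KinshipHypothesis("U", (1.0, 0.0, 0.0), "unrelated"),
    "PO": KinshipHypothesis("PO", (0.0, 1.0, 0.0), "parent-offspring"),
    "FS": KinshipHypothesis("FS", (0.25, 0.5, 0.25), "full siblings"),
    "HS": KinshipHypothesis("HS", (0.5, 0.5, 0.0),
                            "half siblings; same likelihood as grandparent and avuncular"),
    "SELF": KinshipHypothesis("SELF", (0.0, 0.0, 1.0), "self/monozygotic"),
}

# Maximum-likelihood tie-break order: ties go to the less related category.
ML_PRIORITY = ("U", "HS", "FS", "PO", "SELF")


def _as_hypothesis(hyp) -> KinshipHypothesis:
    if isinstance(hyp, KinshipHypothesis):
        return hyp
    return HYPOTHESES[hyp]


@dataclass(frozen=True)
class ErrorModel:
    """Constant, independent per-allele genotyping error.

    In ``freq_draw`` mode an observed allele equals the true allele with
    probability ``1 − epsilon`` and is otherwise replaced by a draw from the
    population allele frequencies (self-replacement allowed).  In
    ``uniform_other`` mode the replacement is uniform over the other
    alleles.  ``epsilon = 0`` reduces every transition matrix to identity.
    """

    epsilon: float = 0.0077
    mode: str = "freq_draw"

    def __post_init__(self):
        if not 0.0 <= self.epsilon < 0.5:
            raise ValueError(f"epsilon {self.epsilon} outside [0, 0.5)")
        if self.mode not in ("freq_draw", "uniform_other"):
            raise ValueError(f"unknown error-model mode {self.mode!r}")

    def allele_transition(self, locus: LocusModel) -> np.ndarray:
        """Matrix ``A[obs, true] = P(observed allele | true allele)``."""
        k = locus.n_alleles
        eye = np.eye(k)
        if self.epsilon == 0.0 or k == 1:
            return eye
        if self.mode == "freq_draw":
            return (1.0 - self.epsilon) * eye + self.epsilon * locus.freqs[:, None]
        off = self.epsilon / (k - 1)
        return (1.0 - self.epsilon) * eye + off * (1.0 - eye)


# ---------------------------------------------------------------------------
# Single-locus probabilities (reference, non-cached path)


def hwe_genotype_prob(call, locus: LocusModel) -> float:
    """Hardy–Weinberg probability of an unordered genotype (2pq for hets)."""
    a, b = call
    pa, pb = locus.freqs[_aidx(locus, a)], locus.freqs[_aidx(locus, b)]
    return float(pa * pb * (1.0 if a == b else 2.0))


def po_transition_prob(parent_call, child_call, locus: LocusModel) -> float:
    """P(child genotype | parent genotype) under Mendelian transmission.

    The parent transmits each of its alleles with probability 1/2; the
    child's other allele is a population draw.
    """
    p = locus.freqs
    total = 0.0
    for transmitted in parent_call:
        c, d = child_call
        if c == d:
            contrib = p[_aidx(locus, c)] if c == transmitted else 0.0
        elif c == transmitted:
            contrib = p[_aidx(locus, d)]
        elif d == transmitted:
            contrib = p[_aidx(locus, c)]
        else:
            contrib = 0.0
        total += 0.5 * contrib
    return float(total)


def _aidx(locus: LocusModel, allele) -> int:
    try:
        return locus.alleles.index(allele)
    except ValueError:
        raise ValueError(f"allele {allele!r} not in catalogue of locus {locus.name}") from None


def true_pair_prob(g1, g2, locus: LocusModel, hyp) -> float:
    """P(true genotype pair | kinship) at one locus.

    ``g1``/``g2`` are unordered allele pairs.  Symmetric in its genotype
    arguments (the one-IBD-allele term is averaged over both orderings,
    which are equal analytically).
    """
    hyp = _as_hypothesis(hyp)
    g1, g2 = _canonical_call(*g1), _canonical_call(*g2)
    k0, k1, k2 = hyp.kappa
    p1, p2 = hwe_genotype_prob(g1, locus), hwe_genotype_prob(g2, locus)
    out = k0 * p1 * p2
    if k1:
        out += k1 * 0.5 * (p1 * po_transition_prob(g1, g2, locus)
                           + p2 * po_transition_prob(g2, g1, locus))
    if k2 and g1 == g2:
        out += k2 * p1
    return float(out)


# ---------------------------------------------------------------------------
# Cached per-locus tables


@dataclass
class _LocusTables:
    """Genotype-indexed probability tables for one locus."""

    locus: LocusModel
    genotypes: list            # unordered allele-index pairs (i, j), i <= j
    geno_index: np.ndarray     # k x k -> genotype index
    hwe: np.ndarray            # HWE probability per genotype
    err_geno: np.ndarray       # E[obs_genotype, true_genotype]
    obs_prob: dict             # hyp label -> G x G observed-pair probability
    logratio: dict             # hyp label -> log(obs_prob[hyp] / obs_prob[U])

    def call_index(self, call) -> int:
        i = _aidx(self.locus, call[0])
        j = _aidx(self.locus, call[1])
        return int(self.geno_index[i, j])


def _build_locus_tables(locus: LocusModel, error: ErrorModel,
                        labels: Sequence[str]) -> _LocusTables:
    k = locus.n_alleles
    p = locus.freqs
    genotypes = [(i, j) for i in range(k) for j in range(i, k)]
    G = len(genotypes)
    geno_index = np.full((k, k), -1, dtype=int)
    for g, (i, j) in enumerate(genotypes):
        geno_index[i, j] = geno_index[j, i] = g

    hwe = np.array([p[i] * p[j] * (1.0 if i == j else 2.0) for i, j in genotypes])

    # Mendelian transition T[parent_g, child_g].
    T = np.zeros((G, G))
    for g1, (a, b) in enumerate(genotypes):
        for g2, (c, d) in enumerate(genotypes):
            total = 0.0
            for t in (a, b):
                if c == d:
                    total += 0.5 * (p[c] if c == t else 0.0)
                elif c == t:
                    total += 0.5 * p[d]
                elif d == t:
                    total += 0.5 * p[c]
            T[g1, g2] = total

    # Genotype-level error channel E[obs, true]; columns sum to 1.
    A = error.allele_transition(locus)
    E = np.zeros((G, G))
    for gt, (a, b) in enumerate(genotypes):
        for go, (c, d) in enumerate(genotypes):
            if c == d:
                E[go, gt] = A[c, a] * A[c, b]
            else:
                E[go, gt] = A[c, a] * A[d, b] + A[d, a] * A[c, b]
    col_sums = E.sum(axis=0)
    if not np.allclose(col_sums, 1.0, atol=1e-12):
        raise AssertionError(f"{locus.name}: error-channel columns sum to {col_sums}")

    obs_prob, logratio = {}, {}
    need = set(labels) | {"U"}
    for label in need:
        k0, k1, k2 = HYPOTHESES[label].kappa
        M = k0 * np.outer(hwe, hwe) + k1 * (hwe[:, None] * T) + k2 * np.diag(hwe)
        M = 0.5 * (M + M.T)
        X = E @ M @ E.T
        obs_prob[label] = 0.5 * (X + X.T)
    with np.errstate(divide="ignore"):
        log_u = np.log(obs_prob["U"])
        for label in need:
            logratio[label] = np.log(obs_prob[label]) - log_u
    return _LocusTables(locus, genotypes, geno_index, hwe, E, obs_prob, logratio)


class KinshipModelContext:
    """Cached P(observed genotype pair | kinship) tables over all loci.

    Parameters
    ----------
    loci : sequence of LocusModel
        Population allele frequencies, normally estimated from the sample.
    error : ErrorModel
        Per-allele genotyping error channel.
    hypotheses : iterable of str, optional
        Hypothesis labels to pre-compute (default: all five).
    """

    def __init__(self, loci: Sequence[LocusModel], error: ErrorModel | None = None,
                 hypotheses: Iterable[str] | None = None):
        self.loci = list(loci)
        self.error = error or ErrorModel()
        labels = tuple(hypotheses) if hypotheses is not None else tuple(HYPOTHESES)
        self.hypothesis_labels = tuple(dict.fromkeys(labels + ("U",)))
        self.tables = [_build_locus_tables(l, self.error, self.hypothesis_labels)
                       for l in self.loci]
        self._locus_pos = {l.name: i for i, l in enumerate(self.loci)}

    def locus_position(self, locus) -> int:
        if isinstance(locus, int):
            return locus
        return self._locus_pos[str(locus)]

    @property
    def locus_names(self) -> tuple:
        return tuple(l.name for l in self.loci)


def observed_pair_prob(g1, g2, ctx: KinshipModelContext, hyp, locus=0) -> float:
    """P(observed genotype pair | kinship) at one locus, error included.

    Strictly positive whenever ``epsilon > 0``; reduces exactly to
    :func:`true_pair_prob` when ``epsilon = 0``.
    """
    hyp = _as_hypothesis(hyp)
    tab = ctx.tables[ctx.locus_position(locus)]
    gi = tab.call_index(_canonical_call(*g1))
    gj = tab.call_index(_canonical_call(*g2))
    return float(tab.obs_prob[hyp.label][gi, gj])


def lod(genotype1: Genotype, genotype2: Genotype, ctx: KinshipModelContext, hyp) -> float:
    """Natural-log likelihood ratio of ``hyp`` versus unrelated.

    Summed over loci typed in both genotypes.  Returns ``nan`` when the
    pair shares no typed locus (unscorable); ``-inf`` is possible only at
    ``epsilon = 0`` (a Mendelian-incompatible locus).
    """
    hyp = _as_hypothesis(hyp)
    if hyp.label == "U":
        return 0.0 if _n_shared(genotype1, genotype2) else float("nan")
    total, shared = 0.0, 0
    for pos, (c1, c2) in enumerate(zip(genotype1.calls, genotype2.calls)):
        if c1 is None or c2 is None:
            continue
        tab = ctx.tables[pos]
        total += tab.logratio[hyp.label][tab.call_index(c1), tab.call_index(c2)]
        shared += 1
    return total if shared else float("nan")


def _n_shared(g1: Genotype, g2: Genotype) -> int:
    return sum(a is not None and b is not None for a, b in zip(g1.calls, g2.calls))


# ---------------------------------------------------------------------------
# Vectorised scoring of many pairs


def encode_genotypes(genotypes: Sequence[Genotype], ctx: KinshipModelContext) -> np.ndarray:
    """(n, n_loci) genotype-index codes; -1 marks a missing locus."""
    n, L = len(genotypes), len(ctx.loci)
    codes = np.full((n, L), -1, dtype=np.int32)
    for i, g in enumerate(genotypes):
        for pos in range(L):
            call = g.calls[pos]
            if call is not None:
                codes[i, pos] = ctx.tables[pos].call_index(call)
    return codes


def pairwise_lod(codes: np.ndarray, ctx: KinshipModelContext, hyp,
                 ii: np.ndarray, jj: np.ndarray) -> np.ndarray:
    """LOD of hypothesis ``hyp`` for the pairs ``(ii[t], jj[t])``."""
    label = _as_hypothesis(hyp).label
    total = np.zeros(len(ii))
    shared = np.zeros(len(ii), dtype=np.int32)
    for pos in range(len(ctx.loci)):
        ci, cj = codes[ii, pos], codes[jj, pos]
        ok = (ci >= 0) & (cj >= 0)
        if label != "U":
            lr = ctx.tables[pos].logratio[label]
            total[ok] += lr[ci[ok], cj[ok]]
        shared += ok
    total[shared == 0] = np.nan
    return total


def ml_category(lods: Mapping[str, float]) -> str | None:
    """Argmax hypothesis, ties broken toward the less related category."""
    finite = {k: v for k, v in lods.items() if v == v}  # drop nan
    if not finite:
        return None
    best_label, best = None, -np.inf
    for label in ML_PRIORITY:
        if label in finite and finite[label] > best:
            best_label, best = label, finite[label]
    return best_label


@dataclass(frozen=True)
class PairScore:
    """LOD scores of one unordered pair under each hypothesis.

    ``lod['U']`` is 0 by construction; ``ml_category`` is the argmax with
    ties to the less related category, or ``None`` for unscorable pairs.
    """

    id_i: str
    id_j: str
    lod: Mapping[str, float]
    n_loci_used: int
    ml_category: str | None


def score_all_pairs(individuals: Sequence[SampleRecord], ctx: KinshipModelContext,
                    hypotheses: Sequence[str] = ("PO", "FS", "HS")) -> list:
    """Score every unordered pair of individuals under each hypothesis.

    Returns ``n(n-1)/2`` :class:`PairScore` objects (SELF is reserved for
    deduplication and not part of the default maximum-likelihood set).
    """
    n = len(individuals)
    if n < 2:
        raise ValueError("need at least 2 individuals")
    labels = [l for l in hypotheses if l != "U"]
    codes = encode_genotypes([s.genotype for s in individuals], ctx)
    ii, jj = np.triu_indices(n, 1)

    lod_arrays = {"U": np.zeros(len(ii))}
    shared = np.zeros(len(ii), dtype=np.int32)
    for pos in range(len(ctx.loci)):
        ci, cj = codes[ii, pos], codes[jj, pos]
        shared += (ci >= 0) & (cj >= 0)
    for label in labels:
        lod_arrays[label] = pairwise_lod(codes, ctx, label, ii, jj)
    lod_arrays["U"][shared == 0] = np.nan

    # Vectorised argmax with ties to the less related category.
    order = [l for l in ML_PRIORITY if l in lod_arrays]
    stacked = np.vstack([lod_arrays[l] for l in order])
    stacked = np.where(np.isnan(stacked), -np.inf, stacked)
    best = stacked.max(axis=0)
    pick = np.argmax(stacked == best[None, :], axis=0)

    ids = [s.sample_id for s in individuals]
    scores = []
    for t in range(len(ii)):
        lods = {l: float(lod_arrays[l][t]) for l in lod_arrays}
        cat = None if shared[t] == 0 else order[pick[t]]
        scores.append(PairScore(ids[ii[t]], ids[jj[t]], lods, int(shared[t]), cat))
    return scores


def pairs_to_frame(pairscores: Sequence[PairScore]) -> "pd.DataFrame":
    """PairScore table as a DataFrame (CSV-ready)."""
    import pandas as pd

    rows = []
    for s in pairscores:
        row = {"id_i": s.id_i, "id_j": s.id_j}
        for label, value in sorted(s.lod.items()):
            row[f"lod_{label}"] = value
        row["n_loci_used"] = s.n_loci_used
        row["ml_category"] = s.ml_category
        rows.append(row)
    return pd.DataFrame(rows)
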
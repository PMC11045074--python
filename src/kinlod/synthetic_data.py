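"""Synthetic populations with known pedigree truth.

The study's raw genotypes are available only on request, so every pipeline
stage is exercised on generated data emulating their shape: ~171
individuals typed at 14 microsatellite loci carrying 2–15 alleles each,
Hardy–Weinberg genotype proportions, a per-allele typing error around
0.0077, maternally inherited mtDNA haplotypes from a pool of ~8, close-kin
pairs embedded by Mendelian transmission, duplicate and re-sampled
biopsies, and sampling events concentrated at 85°–135°E south of 60°S over
the 1993–2019 austral summer seasons.

Three generators are exposed:

* :func:`simulate_population` — a general multi-generation pedigree with a
  full relationship truth table (PO/FS/HS/GP/AV/U);
* :func:`study_fixture` — a pinned 183-sample bundle collapsing to
  171 individuals (4 same-place/time duplicates, 8 resamples) with planted
  PO/HS/FS pairs, one triad and field-flagged mother–calf pairs;
* :func:`planted_kin_sample` — unrelated individuals plus a chosen number
  of independent parent–offspring pairs, for recovery experiments.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import datetime as _dt
import itertools
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .genotype_io import Genotype, LocusModel, SampleRecord
from .kinship_model import ErrorModel

logger = logging.getLogger(__name__)

__all__ = [
    "SimConfig",
    "TruthTable",
    "FixtureBundle",
    "random_locus_models",
    "simulate_population",
    "study_fixture",
    "planted_kin_sample",
    "planted_tail_shift_pairs",
]


@dataclass(frozen=True)
class SimConfig:
    """Generator settings; defaults mirror the study's sampling conditions."""

    n_founders: int = 100
    n_generations: int = 2
    n_offspring_per_generation: int = 40
    n_loci: int = 14
    alleles_per_locus: tuple = (2, 15)
    allele_freq_concentration: float = 1.0
    epsilon: float = 0.0077
    error_mode: str = "freq_draw"
    n_mtdna_haplotypes: int = 8
    sex_ratio: float = 0.5
    sampling_years: tuple = (1993, 2019)
    sector_center: tuple = (-64.0, 110.0)   # (lat, lon) degrees
    sector_spread: tuple = (1.5, 12.0)      # (lat, lon) s.d. degrees
    p_low_latitude: float = 0.08            # occasional lower-latitude events
    n_vessels: int = 6
    n_duplicates: int = 0
    n_resamples: int = 0
    p_mother_calf_event: float = 0.0
    adult_length_m: tuple = (13.5, 1.2)     # (mean, s.d.)
    calf_length_m: tuple = (10.0, 0.8)
    seed: int = 0

    def __post_init__(self):
        if min(self.n_founders, self.n_loci, self.n_mtdna_haplotypes) < 1:
            raise ValueError("counts must be positive")
        for p in (self.sex_ratio, self.p_mother_calf_event, self.p_low_latitude):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


def random_locus_models(rng: np.random.Generator, n_loci: int = 14,
                        alleles_per_locus: tuple = (2, 15),
                        concentration: float = 1.0) -> list:
    """Dirichlet-sampled allele frequencies for microsatellite-like loci.

    Allele labels are fragment-size-like integers.  Frequencies are floored
    at 1e-6 (then renormalised) so every catalogued allele is drawable.
    """
    lo, hi = alleles_per_locus
    models = []
    for k in range(n_loci):
        n_alleles = int(rng.integers(lo, hi + 1))
        freqs = rng.dirichlet(np.full(n_alleles, concentration))
        freqs = np.maximum(freqs, 1e-6)
        freqs /= freqs.sum()
        alleles = tuple(100 + 4 * a for a in range(n_alleles))
        models.append(LocusModel(f"L{k + 1:02d}", alleles, freqs))
    return models


# ---------------------------------------------------------------------------
# Low-level drawing helpers (allele-index space)


def _draw_founder(rng, loci) -> list:
    return [tuple(rng.choice(l.n_alleles, size=2, p=l.freqs)) for l in loci]


def _mendelian_child(rng, mother: list, father: list, loci) -> list:
    child = []
    for (ma, mb), (fa, fb) in zip(mother, father):
        child.append((ma if rng.random() < 0.5 else mb,
                      fa if rng.random() < 0.5 else fb))
    return child


def _po_child(rng, parent: list, loci) -> list:
    """Child of ``parent`` and an unsampled random mate."""
    child = []
    for (pa, pb), locus in zip(parent, loci):
        inherited = pa if rng.random() < 0.5 else pb
        other = int(rng.choice(locus.n_alleles, p=locus.freqs))
        child.append((inherited, other))
    return child


def _observe(rng, true_geno: list, loci, error: ErrorModel) -> Genotype:
    """Apply the per-allele error channel and build a Genotype."""
    calls = []
    for (a, b), locus in zip(true_geno, loci):
        oa, ob = a, b
        if error.epsilon > 0 and locus.n_alleles > 1:
            if rng.random() < error.epsilon:
                oa = _err_allele(rng, oa, locus, error)
            if rng.random() < error.epsilon:
                ob = _err_allele(rng, ob, locus, error)
        calls.append((locus.alleles[oa], locus.alleles[ob]))
    return Genotype(tuple(l.name for l in loci), calls)


def _err_allele(rng, true_idx: int, locus: LocusModel, error: ErrorModel) -> int:
    if error.mode == "freq_draw":
        return int(rng.choice(locus.n_alleles, p=locus.freqs))
    return int((true_idx + rng.integers(1, locus.n_alleles)) % locus.n_alleles)


def _season_date(rng, year: int) -> _dt.date:
    """A date in the austral summer season starting in December of ``year``."""
    return _dt.date(year, 12, 1) + _dt.timedelta(days=int(rng.integers(0, 120)))


def _position(rng, config: SimConfig) -> tuple:
    lat_c, lon_c = config.sector_center
    lat_s, lon_s = config.sector_spread
    if rng.random() < config.p_low_latitude:
        lat = float(np.clip(rng.normal(-37.0, 2.0), -45.0, -33.0))
    else:
        lat = float(np.clip(rng.normal(lat_c, lat_s), -78.0, -50.0))
    lon = float(rng.normal(lon_c, lon_s))
    lon = (lon + 180.0) % 360.0 - 180.0
    if lon == -180.0:
        lon = 180.0
    return lat, lon


# ---------------------------------------------------------------------------
# Truth bookkeeping


@dataclass
class TruthTable:
    """Ground truth: sample → individual map and pairwise relationships.

    ``relationships`` holds only related individual pairs (keyed by a
    frozenset of two individual ids); everything else is unrelated.
    """

    individual_of: Mapping[str, str]
    relationships: Mapping[frozenset, str]

    def relationship(self, a: str, b: str) -> str:
        ia = self.individual_of.get(a, a)
        ib = self.individual_of.get(b, b)
        if ia == ib:
            return "SELF"
        return self.relationships.get(frozenset((ia, ib)), "U")

    def pairs_of(self, label: str) -> list:
        return sorted(tuple(sorted(k)) for k, v in self.relationships.items() if v == label)


def _pedigree_relationship(a: str, b: str, parents: Mapping) -> str:
    """Classify a pair from the pedigree: PO/FS/HS/GP/AV, else U."""
    pa = set(filter(None, parents.get(a, ())))
    pb = set(filter(None, parents.get(b, ())))
    if a in pb or b in pa:
        return "PO"
    if pa and pa == pb:
        return "FS"
    if pa & pb:
        return "HS"
    grand_a = {g for p in pa for g in filter(None, parents.get(p, ()))}
    grand_b = {g for p in pb for g in filter(None, parents.get(p, ()))}
    if a in grand_b or b in grand_a:
        return "GP"
    # avuncular: one is a full sibling of the other's parent
    for child, other_parents in ((a, pb), (b, pa)):
        pc = set(filter(None, parents.get(child, ())))
        for p in other_parents:
            pp = set(filter(None, parents.get(p, ())))
            if pc and pc == pp and child not in (None, p):
                return "AV"
    return "U"


# ---------------------------------------------------------------------------
# General pedigree simulation


@dataclass
class _Individual:
    ind_id: str
    genotype: list          # per-locus allele-index pairs (true)
    sex: str
    haplotype: str
    mother: str | None
    father: str | None
    generation: int


def simulate_population(config: SimConfig):
    """Simulate a pedigreed population and its biopsy-sample tables.

    Founders are drawn in Hardy–Weinberg proportions from Dirichlet-sampled
    allele frequencies; each later generation receives one uniformly chosen
    allele per parent per locus, the mother's mtDNA haplotype, and a sex
    drawn from ``sex_ratio``.  Every individual is sampled once; duplicates
    (same place and time) and resamples (a later season) add extra
    biopsies, and mother–calf events give both members a shared
    date/vessel/position plus field flags.

    Returns ``(samples, truth, loci)``.
    """
    rng = np.random.default_rng(config.seed)
    loci = random_locus_models(rng, config.n_loci, config.alleles_per_locus,
                               config.allele_freq_concentration)
    error = ErrorModel(config.epsilon, config.error_mode)
    haplos = [f"H{h + 1}" for h in range(config.n_mtdna_haplotypes)]

    individuals: list[_Individual] = []
    for i in range(config.n_founders):
        individuals.append(_Individual(
            f"I{i + 1:04d}", _draw_founder(rng, loci),
            "F" if rng.random() < config.sex_ratio else "M",
            str(rng.choice(haplos)), None, None, 0))

    for gen in range(1, config.n_generations + 1):
        pool = [x for x in individuals if x.generation < gen]
        mothers = [x for x in pool if x.sex == "F"]
        fathers = [x for x in pool if x.sex == "M"]
        if not mothers or not fathers:
            raise ValueError("cannot breed: a previous generation lacks one sex")
        for _ in range(config.n_offspring_per_generation):
            mother = mothers[rng.integers(len(mothers))]
            father = fathers[rng.integers(len(fathers))]
            individuals.append(_Individual(
                f"I{len(individuals) + 1:04d}",
                _mendelian_child(rng, mother.genotype, father.genotype, loci),
                "F" if rng.random() < config.sex_ratio else "M",
                mother.haplotype, mother.ind_id, father.ind_id,
                gen))

    if config.n_duplicates + config.n_resamples > len(individuals):
        raise ValueError("more duplicates/resamples than individuals")

    parents = {x.ind_id: (x.mother, x.father) for x in individuals}
    by_id = {x.ind_id: x for x in individuals}

    # One sampling event per individual.
    samples: list[SampleRecord] = []
    individual_of: dict = {}
    event_count: dict = {}

    def add_sample(ind: _Individual, date, lat, lon, vessel,
                   body_length, field_obs=frozenset()):
        k = event_count.get(ind.ind_id, 0)
        event_count[ind.ind_id] = k + 1
        sid = ind.ind_id if k == 0 else f"{ind.ind_id}.{k + 1}"
        individual_of[sid] = ind.ind_id
        samples.append(SampleRecord(
            sample_id=sid, genotype=_observe(rng, ind.genotype, loci, error),
            sex=ind.sex, mtdna_haplotype=ind.haplotype,
            body_length_m=round(float(body_length), 1),
            date=date, lat=round(lat, 2), lon=round(lon, 2), vessel=vessel,
            field_obs=field_obs))
        return sid

    # Pre-select joint mother-calf sampling events (each member at most once).
    y0, y1 = config.sampling_years
    mc_child, mc_taken = {}, set()
    for ind in individuals:
        if (ind.mother and ind.mother not in mc_taken and ind.ind_id not in mc_taken
                and rng.random() < config.p_mother_calf_event):
            mc_child[ind.mother] = ind.ind_id
            mc_taken.update((ind.mother, ind.ind_id))

    handled = set()
    for ind in individuals:
        if ind.ind_id in handled:
            continue
        year = int(rng.integers(y0, y1 + 1))
        date = _season_date(rng, year)
        lat, lon = _position(rng, config)
        vessel = f"V{rng.integers(config.n_vessels) + 1}"
        mu, sd = config.adult_length_m
        if ind.ind_id in mc_child:
            # joint mother-calf event: shared date, vessel and position
            calf = by_id[mc_child[ind.ind_id]]
            cmu, csd = config.calf_length_m
            sid_m = add_sample(ind, date, lat, lon, vessel, rng.normal(mu, sd))
            sid_c = add_sample(calf, date, lat, lon, vessel, rng.normal(cmu, csd))
            samples[-2] = _with_mc(samples[-2], sid_c)
            samples[-1] = _with_mc(samples[-1], sid_m)
            handled.update((ind.ind_id, calf.ind_id))
        else:
            add_sample(ind, date, lat, lon, vessel, rng.normal(mu, sd))
            handled.add(ind.ind_id)

    # Extra biopsies: duplicates share the first event's place and time,
    # resamples occur in a different season and place.
    eligible = [x for x in individuals if event_count.get(x.ind_id, 0) == 1]
    extra = rng.choice(len(eligible), size=config.n_duplicates + config.n_resamples,
                       replace=False)
    first_event = {s.sample_id: s for s in samples}
    for t, pick in enumerate(extra):
        ind = eligible[int(pick)]
        orig = first_event[ind.ind_id]
        mu, sd = config.adult_length_m
        if t < config.n_duplicates:
            add_sample(ind, orig.date, orig.lat, orig.lon, orig.vessel,
                       rng.normal(mu, sd))
        else:
            year = int(rng.integers(y0, y1 + 1))
            lat, lon = _position(rng, config)
            add_sample(ind, _season_date(rng, year), lat, lon,
                       f"V{rng.integers(config.n_vessels) + 1}", rng.normal(mu, sd))

    relationships = {}
    ids = [x.ind_id for x in individuals]
    for a, b in itertools.combinations(ids, 2):
        rel = _pedigree_relationship(a, b, parents)
        if rel != "U":
            relationships[frozenset((a, b))] = rel
    truth = TruthTable(individual_of, relationships)
    return samples, truth, loci


def _with_mc(record: SampleRecord, partner_sid: str) -> SampleRecord:
    from dataclasses import replace
    return replace(record, field_obs=record.field_obs | {f"MC:{partner_sid}"})


# ---------------------------------------------------------------------------
# Targeted fixtures


@dataclass
class FixtureBundle:
    """A pinned synthetic dataset plus the identifiers of its planted truth."""

    samples: list
    truth: TruthTable
    loci: list
    seed: int
    po_pairs: list = field(default_factory=list)
    hs_pairs: list = field(default_factory=list)
    fs_pairs: list = field(default_factory=list)
    triad: tuple = ()
    mc_pairs: list = field(default_factory=list)
    duplicate_ids: list = field(default_factory=list)
    resample_ids: list = field(default_factory=list)


def planted_kin_sample(seed: int, n_individuals: int = 171, n_po: int = 10,
                       loci: Sequence[LocusModel] | None = None,
                       epsilon: float = 0.0077, error_mode: str = "freq_draw"):
    """Unrelated individuals plus ``n_po`` independent parent–offspring pairs.

    Each PO pair occupies two of the ``n_individuals`` slots (parent drawn
    under Hardy–Weinberg, child by Mendelian transmission from the parent
    and a population draw); all remaining individuals and all cross-pair
    combinations are unrelated.  Returns ``(samples, truth, loci)``.
    """
    if 2 * n_po > n_individuals:
        raise ValueError("too many PO pairs for the sample size")
    rng = np.random.default_rng(seed)
    if loci is None:
        loci = random_locus_models(rng)
    error = ErrorModel(epsilon, error_mode)

    samples, individual_of, relationships = [], {}, {}

    def emit(ind_id: str, true_geno: list, **meta):
        individual_of[ind_id] = ind_id
        year = int(rng.integers(1993, 2020))
        lat, lon = _position(rng, SimConfig())
        samples.append(SampleRecord(
            sample_id=ind_id, genotype=_observe(rng, true_geno, loci, error),
            sex="F" if rng.random() < 0.5 else "M",
            mtdna_haplotype=f"H{rng.integers(8) + 1}",
            date=_season_date(rng, year), lat=round(lat, 2), lon=round(lon, 2),
            vessel=f"V{rng.integers(6) + 1}", **meta))

    for k in range(n_po):
        parent = _draw_founder(rng, loci)
        child = _po_child(rng, parent, loci)
        pid, cid = f"P{k + 1:03d}", f"C{k + 1:03d}"
        emit(pid, parent)
        emit(cid, child)
        relationships[frozenset((pid, cid))] = "PO"
    for k in range(n_individuals - 2 * n_po):
        emit(f"U{k + 1:03d}", _draw_founder(rng, loci))

    return samples, TruthTable(individual_of, relationships), list(loci)


def study_fixture(seed: int) -> FixtureBundle:
    """183 biopsy samples of 171 individuals, shaped like the study data.

    14 loci with 2–15 alleles, per-allele error 0.0077, 8 mtDNA haplotypes,
    near-equal sex ratio, sampling concentrated 85°–135°E south of 60°S
    with a few lower-latitude events in 1993–2019 seasons.  Planted truth:
    ten independent PO pairs plus a mother with two daughters (a triad:
    two more PO pairs whose offspring are half sisters), three HS pairs and
    one FS pair; four of the PO pairs are field-flagged mother–calf events.
    Four duplicate biopsies (same place and time) and eight resamples bring
    the sample count from 171 to 183.
    """
    rng = np.random.default_rng(seed)
    loci = random_locus_models(rng)
    error = ErrorModel(0.0077)
    config = SimConfig(seed=seed)

    samples: list[SampleRecord] = []
    individual_of: dict = {}
    relationships: dict = {}
    true_geno: dict = {}
    meta: dict = {}

    def new_ind(ind_id, geno, sex, haplo, length=None):
        true_geno[ind_id] = geno
        meta[ind_id] = {"sex": sex, "haplotype": haplo, "length": length}

    def rand_haplo():
        return f"H{rng.integers(8) + 1}"

    def adult_len():
        return round(float(rng.normal(*config.adult_length_m)), 1)

    def calf_len():
        return round(float(rng.normal(*config.calf_length_m)), 1)

    po_pairs, hs_pairs, fs_pairs, mc_pairs = [], [], [], []

    # Ten independent PO pairs; the first four are mother-calf field events.
    for k in range(10):
        pid, cid = f"W{2 * k + 1:03d}", f"W{2 * k + 2:03d}"
        parent = _draw_founder(rng, loci)
        child = _po_child(rng, parent, loci)
        is_mc = k < 4
        if is_mc:
            p_hap = rand_haplo()
            new_ind(pid, parent, "F", p_hap, adult_len())
            new_ind(cid, child, "F" if rng.random() < 0.5 else "M", p_hap, calf_len())
            mc_pairs.append((pid, cid))
        else:
            maternal = rng.random() < 0.5
            p_hap, c_hap = rand_haplo(), None
            c_hap = p_hap if maternal else rand_haplo()
            p_sex = "F" if maternal else "M"
            new_ind(pid, parent, p_sex, p_hap, adult_len())
            new_ind(cid, child, "F" if rng.random() < 0.5 else "M", c_hap, adult_len())
        po_pairs.append((pid, cid))
        relationships[frozenset((pid, cid))] = "PO"

    # Triad: mother W021 and daughters W022, W023 (half sisters: different
    # unsampled fathers).
    mother = _draw_founder(rng, loci)
    m_hap = rand_haplo()
    new_ind("W021", mother, "F", m_hap, adult_len())
    for cid in ("W022", "W023"):
        new_ind(cid, _po_child(rng, mother, loci), "F", m_hap, adult_len())
        relationships[frozenset(("W021", cid))] = "PO"
        po_pairs.append(("W021", cid))
    relationships[frozenset(("W022", "W023"))] = "HS"
    hs_pairs.append(("W022", "W023"))
    triad = ("W021", "W022", "W023")

    # Three half-sib pairs (shared unsampled parent) and one full-sib pair.
    next_id = 24
    for _ in range(3):
        shared = _draw_founder(rng, loci)
        a, b = f"W{next_id:03d}", f"W{next_id + 1:03d}"
        next_id += 2
        maternal = rng.random() < 0.5
        hap = rand_haplo()
        for x in (a, b):
            new_ind(x, _po_child(rng, shared, loci),
                    "F" if rng.random() < 0.5 else "M",
                    hap if maternal else rand_haplo(), adult_len())
        relationships[frozenset((a, b))] = "HS"
        hs_pairs.append((a, b))
    shared_m, shared_f = _draw_founder(rng, loci), _draw_founder(rng, loci)
    a, b = f"W{next_id:03d}", f"W{next_id + 1:03d}"
    next_id += 2
    hap = rand_haplo()
    for x in (a, b):
        new_ind(x, _mendelian_child(rng, shared_m, shared_f, loci),
                "F" if rng.random() < 0.5 else "M", hap, adult_len())
    relationships[frozenset((a, b))] = "FS"
    fs_pairs.append((a, b))

    while next_id <= 171:
        new_ind(f"W{next_id:03d}", _draw_founder(rng, loci),
                "F" if rng.random() < 0.5 else "M", rand_haplo(), adult_len())
        next_id += 1

    # Sampling events: one per individual; MC pairs share date/vessel/position.
    events: dict = {}
    y0, y1 = config.sampling_years
    for ind_id in true_geno:
        year = int(rng.integers(y0, y1 + 1))
        lat, lon = _position(rng, config)
        events[ind_id] = {"date": _season_date(rng, year),
                          "lat": round(lat, 2), "lon": round(lon, 2),
                          "vessel": f"V{rng.integers(config.n_vessels) + 1}"}
    for pid, cid in mc_pairs:
        events[cid] = dict(events[pid])

    def emit(ind_id, suffix="", field_obs=frozenset()):
        sid = ind_id + suffix
        individual_of[sid] = ind_id
        ev = events[ind_id] if not suffix else None
        if suffix == ".d":      # duplicate: same place and time, re-typed
            ev = events[ind_id]
        elif suffix == ".r":    # resample: different season and place
            year = int(rng.integers(y0, y1 + 1))
            lat, lon = _position(rng, config)
            ev = {"date": _season_date(rng, year), "lat": round(lat, 2),
                  "lon": round(lon, 2), "vessel": f"V{rng.integers(config.n_vessels) + 1}"}
        m = meta[ind_id]
        samples.append(SampleRecord(
            sample_id=sid,
            genotype=_observe(rng, true_geno[ind_id], loci, error),
            sex=m["sex"], mtdna_haplotype=m["haplotype"],
            body_length_m=m["length"], date=ev["date"], lat=ev["lat"],
            lon=ev["lon"], vessel=ev["vessel"], field_obs=field_obs))

    mc_flags = {}
    for pid, cid in mc_pairs:
        mc_flags[pid] = frozenset({f"MC:{cid}"})
        mc_flags[cid] = frozenset({f"MC:{pid}"})
    for ind_id in true_geno:
        emit(ind_id, field_obs=mc_flags.get(ind_id, frozenset()))

    # 4 duplicates + 8 resamples -> 183 samples; drawn from the unrelated pool.
    pool = [i for i in true_geno if i.startswith("W") and int(i[1:]) > 40]
    extra = rng.choice(len(pool), size=12, replace=False)
    duplicate_ids = [pool[int(i)] for i in extra[:4]]
    resample_ids = [pool[int(i)] for i in extra[4:]]
    for ind_id in duplicate_ids:
        emit(ind_id, suffix=".d")
    for ind_id in resample_ids:
        emit(ind_id, suffix=".r")

    return FixtureBundle(
        samples=samples, truth=TruthTable(individual_of, relationships),
        loci=loci, seed=seed, po_pairs=po_pairs, hs_pairs=hs_pairs,
        fs_pairs=fs_pairs, triad=triad, mc_pairs=mc_pairs,
        duplicate_ids=duplicate_ids, resample_ids=resample_ids)


# ---------------------------------------------------------------------------
# Planted quantile-regression effect


def planted_tail_shift_pairs(seed: int, n: int = 10000, frac_same_day: float = 0.12,
                             shift: float = 1.8, ramp: tuple = (0.91, 0.94),
                             base_loc: float = -8.0, base_scale: float = 3.0) -> list:
    """Pairs whose SameDayPos stratum is LOD-shifted only in the upper tail.

    Each pair draws a latent uniform ``u`` mapped through a Normal base
    quantile function; SameDayPos pairs additionally gain ``shift·w(u)``
    where ``w`` ramps from 0 (u ≤ ramp[0]) to 1 (u ≥ ramp[1]).  By the
    inverse-CDF argument the between-stratum τ-quantile difference is
    exactly 0 for τ ≤ ramp[0] and exactly ``shift`` for τ ≥ ramp[1] —
    the signature of tail-concentrated relatives among pairs sampled close
    in time and space.  Δ longitude is independent noise (zero true slope).
    The default ``n`` matches the scale of a ~1.2e4-pair sector analysis;
    at a few thousand pairs the bootstrap distribution of the SameDayPos
    tail coefficient turns bimodal (resampled group quantiles fall below
    the ramp) and the experiment loses power.
    """
    from scipy import stats as _st

    from .spatial_stats import SpatialPair

    rng = np.random.default_rng(seed)
    u = rng.random(n)
    same_day = rng.random(n) < frac_same_day
    lo, hi = ramp
    w = np.clip((u - lo) / (hi - lo), 0.0, 1.0)
    lod_hs = _st.norm.ppf(u, loc=base_loc, scale=base_scale) + shift * w * same_day
    dlon = rng.uniform(0.0, 50.0, size=n)
    return [
        SpatialPair(f"A{k}", f"B{k}", float(dlon[k]), bool(same_day[k]),
                    lod_hs=float(lod_hs[k]), lod_po=float("nan"), ml_category="U")
        for k in range(n)
    ]
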
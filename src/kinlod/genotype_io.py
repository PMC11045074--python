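"""Genotype and metadata tables: reading, writing, allele frequencies, QC.

Input data are diploid microsatellite genotypes (one unordered allele pair
per locus, missing loci allowed) together with per-sample metadata (sex,
mtDNA haplotype, visually estimated body length, sampling date/position,
vessel, field observations).  Two genotype-table dialects are supported:

* ``wide``   — CSV/TSV with columns ``sample_id, <locus>_1, <locus>_2``;
* ``packed`` — CSV/TSV with one column per locus holding ``a1/a2``;
* ``genepop``— a standard GenePop file (2- or 3-digit allele codes,
  ``0`` = missing).

This module also owns duplicate/resample detection (two biopsies of the
same individual), which reuses the self/monozygotic LOD score from
:mod:`kinlod.kinship_model`, and a chi-square Hardy–Weinberg check.
"""

from __future__ import annotations

import csv
import datetime as _dt
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "LocusModel",
    "Genotype",
    "SampleRecord",
    "DuplicateGroup",
    "DedupResult",
    "HWEResult",
    "IOConfig",
    "read_samples",
    "write_samples",
    "estimate_allele_freqs",
    "deduplicate",
    "hwe_check",
]

# Sentinel metadata values meaning "unknown".
UNKNOWN = None


@dataclass(frozen=True)
class LocusModel:
    """Allele catalogue and population allele frequencies for one locus.

    Frequencies must be strictly positive and sum to one (tolerance 1e-12).
    A monomorphic locus (a single allele) is representable — it carries no
    kinship information and is flagged by :attr:`is_monomorphic`.
    """

    name: str
    alleles: tuple
    freqs: np.ndarray

    def __post_init__(self):
        freqs = np.asarray(self.freqs, dtype=float)
        object.__setattr__(self, "freqs", freqs)
        object.__setattr__(self, "alleles", tuple(self.alleles))
        if len(self.alleles) != freqs.size:
            raise ValueError(f"{self.name}: {len(self.alleles)} alleles vs {freqs.size} freqs")
        if len(self.alleles) == 0:
            raise ValueError(f"{self.name}: empty allele catalogue")
        if len(set(self.alleles)) != len(self.alleles):
            raise ValueError(f"{self.name}: duplicate allele labels")
        if np.any(freqs <= 0):
            raise ValueError(f"{self.name}: allele frequencies must be > 0")
        if abs(freqs.sum() - 1.0) > 1e-12:
            raise ValueError(f"{self.name}: frequencies sum to {freqs.sum()!r}, not 1")

    @property
    def n_alleles(self) -> int:
        return len(self.alleles)

    @property
    def is_monomorphic(self) -> bool:
        return len(self.alleles) == 1

    def index(self, allele) -> int:
        return self.alleles.index(allele)


def _canonical_call(a, b):
    """Unordered allele pair as a sorted tuple (representation-independent)."""
    return (a, b) if _le(a, b) else (b, a)


def _le(a, b):
    try:
        return a <= b
    except TypeError:  # mixed str/int labels — compare as strings
        return str(a) <= str(b)


@dataclass(frozen=True)
class Genotype:
    """A multilocus diploid genotype.

    ``calls[k]`` is the unordered allele pair at locus ``loci[k]`` stored as
    a sorted tuple, or ``None`` when the locus is untyped.  Equality is
    therefore independent of the order alleles were listed in.
    """

    loci: tuple
    calls: tuple

    def __post_init__(self):
        loci = tuple(self.loci)
        calls = tuple(None if c is None else _canonical_call(*c) for c in self.calls)
        if len(loci) != len(calls):
            raise ValueError("loci and calls length mismatch")
        object.__setattr__(self, "loci", loci)
        object.__setattr__(self, "calls", calls)

    @property
    def n_typed(self) -> int:
        return sum(c is not None for c in self.calls)

    def call(self, locus_name: str):
        return self.calls[self.loci.index(locus_name)]


@dataclass(frozen=True)
class SampleRecord:
    """One biopsy sample: genotype plus field metadata.

    Unknown metadata are ``None``.  ``field_obs`` is a set of flags; a
    field-observed mother–calf link to another sample is encoded as
    ``"MC:<other_sample_id>"``.
    """

    sample_id: str
    genotype: Genotype
    sex: str | None = None  # "F" | "M" | None
    mtdna_haplotype: str | None = None
    body_length_m: float | None = None
    date: _dt.date | None = None
    lat: float | None = None
    lon: float | None = None
    vessel: str | None = None
    field_obs: frozenset = frozenset()

    def __post_init__(self):
        if self.sex not in (None, "F", "M"):
            raise ValueError(f"{self.sample_id}: sex must be F, M or unknown")
        if self.lat is not None and not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"{self.sample_id}: latitude {self.lat} out of range")
        if self.lon is not None and not -180.0 < self.lon <= 180.0:
            raise ValueError(f"{self.sample_id}: longitude {self.lon} out of (-180, 180]")
        if self.body_length_m is not None and self.body_length_m <= 0:
            raise ValueError(f"{self.sample_id}: non-positive body length")
        object.__setattr__(self, "field_obs", frozenset(self.field_obs))

    def mc_partner(self) -> str | None:
        """Sample id of the field-observed mother–calf partner, if any."""
        for flag in self.field_obs:
            if flag.startswith("MC:"):
                return flag[3:]
        return None


@dataclass(frozen=True)
class DuplicateGroup:
    sample_ids: tuple
    kind: str  # "same_place_time_duplicate" | "resample"
    retained_id: str


@dataclass
class DedupResult:
    unique_individuals: list
    duplicate_groups: list
    n_input: int

    def __post_init__(self):
        merged_away = sum(len(g.sample_ids) - 1 for g in self.duplicate_groups)
        if len(self.unique_individuals) + merged_away != self.n_input:
            raise ValueError("dedup bookkeeping does not reconcile with input count")

    @property
    def n_unique(self) -> int:
        return len(self.unique_individuals)


@dataclass(frozen=True)
class HWEResult:
    locus: str
    statistic: float
    df: int
    pvalue: float
    testable: bool
    note: str = ""


@dataclass(frozen=True)
class IOConfig:
    """Table-dialect settings for :func:`read_samples`/:func:`write_samples`."""

    dialect: str = "wide"  # "wide" | "packed" | "genepop"
    sep: str = ","
    packed_sep: str = "/"
    missing_codes: tuple = ("0", "", "NA", "-", "?")
    date_min: _dt.date = _dt.date(1950, 1, 1)
    date_max: _dt.date = _dt.date(2035, 12, 31)


# ---------------------------------------------------------------------------
# Reading and writing


def _parse_allele(token: str):
    token = token.strip()
    try:
        return int(token)
    except ValueError:
        return token


def _read_genotype_table(path: Path, config: IOConfig):
    """Return (loci, {sample_id: calls list}) for the configured dialect."""
    if config.dialect == "genepop":
        return _read_genepop(path)
    df = pd.read_csv(path, sep=config.sep, dtype=str, keep_default_na=False)
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: genotype table lacks a sample_id column")
    if config.dialect == "wide":
        locus_cols = [c for c in df.columns if c.endswith("_1")]
        loci = [c[:-2] for c in locus_cols]
        for locus in loci:
            if f"{locus}_2" not in df.columns:
                raise ValueError(f"{path}: column {locus}_2 missing (dialect 'wide')")
    elif config.dialect == "packed":
        loci = [c for c in df.columns if c != "sample_id"]
    else:
        raise ValueError(f"unknown genotype dialect {config.dialect!r}")

    genotypes = {}
    missing = set(config.missing_codes)
    for _, row in df.iterrows():
        sid = row["sample_id"].strip()
        if sid in genotypes:
            raise ValueError(f"{path}: duplicate sample_id {sid!r}")
        calls = []
        for locus in loci:
            if config.dialect == "wide":
                a, b = row[f"{locus}_1"].strip(), row[f"{locus}_2"].strip()
            else:
                cell = row[locus].strip()
                if cell in missing:
                    calls.append(None)
                    continue
                parts = cell.split(config.packed_sep)
                if len(parts) != 2:
                    logger.warning("%s locus %s: unparseable cell %r -> missing", sid, locus, cell)
                    calls.append(None)
                    continue
                a, b = parts[0].strip(), parts[1].strip()
            if a in missing or b in missing:
                calls.append(None)
            else:
                try:
                    calls.append((_parse_allele(a), _parse_allele(b)))
                except Exception:
                    logger.warning("%s locus %s: unparseable alleles %r/%r -> missing", sid, locus, a, b)
                    calls.append(None)
        genotypes[sid] = calls
    return loci, genotypes


def _read_genepop(path: Path):
    """Minimal reader for the standard diploid GenePop dialect.

    Allele codes are 2 or 3 digits per allele, ``00``/``000`` missing; all
    individuals are pooled regardless of POP blocks (population structure is
    not used downstream).
    """
    lines = Path(path).read_text().splitlines()
    if len(lines) < 3:
        raise ValueError(f"{path}: not a GenePop file")
    body = lines[1:]
    # Locus names: either one per line or a single comma-separated line.
    loci = []
    i = 0
    while i < len(body) and body[i].strip().lower() != "pop":
        loci.extend(tok.strip() for tok in body[i].split(",") if tok.strip())
        i += 1
    genotypes = {}
    for line in body[i:]:
        stripped = line.strip()
        if not stripped or stripped.lower() == "pop":
            continue
        if "," not in stripped:
            raise ValueError(f"{path}: malformed individual line {stripped!r}")
        sid, geno_part = stripped.split(",", 1)
        sid = sid.strip()
        if sid in genotypes:
            raise ValueError(f"{path}: duplicate sample_id {sid!r}")
        tokens = geno_part.split()
        if len(tokens) != len(loci):
            raise ValueError(f"{path}: {sid}: {len(tokens)} genotype fields for {len(loci)} loci")
        calls = []
        for tok in tokens:
            if len(tok) not in (4, 6) or not tok.isdigit():
                logger.warning("%s: unparseable GenePop field %r -> missing", sid, tok)
                calls.append(None)
                continue
            half = len(tok) // 2
            a, b = int(tok[:half]), int(tok[half:])
            calls.append(None if a == 0 or b == 0 else (a, b))
        genotypes[sid] = calls
    return loci, genotypes


def _parse_date(cell: str, config: IOConfig, sid: str):
    cell = cell.strip()
    if not cell:
        return None
    date = _dt.date.fromisoformat(cell)
    if not config.date_min <= date <= config.date_max:
        raise ValueError(f"{sid}: date {date} outside plausible window "
                         f"[{config.date_min}, {config.date_max}]")
    return date


def read_samples(genotype_path, metadata_path, config: IOConfig | None = None) -> list:
    """Read and validate genotype + metadata tables into ``SampleRecord``s.

    The two tables must carry exactly the same sample ids; mismatches are a
    hard error listing the offenders.  Unparseable allele cells degrade to
    missing loci with a logged warning; record count always equals the
    genotype table's data-row count.
    """
    config = config or IOConfig()
    loci, genotypes = _read_genotype_table(Path(genotype_path), config)
    loci_t = tuple(loci)

    meta = pd.read_csv(metadata_path, dtype=str, keep_default_na=False)
    if "sample_id" not in meta.columns:
        raise ValueError(f"{metadata_path}: metadata lacks a sample_id column")
    meta_ids = [s.strip() for s in meta["sample_id"]]
    if len(set(meta_ids)) != len(meta_ids):
        dupes = sorted({s for s in meta_ids if meta_ids.count(s) > 1})
        raise ValueError(f"{metadata_path}: duplicate sample_id(s) {dupes}")
    only_geno = sorted(set(genotypes) - set(meta_ids))
    only_meta = sorted(set(meta_ids) - set(genotypes))
    if only_geno or only_meta:
        raise ValueError(
            "genotype/metadata sample_id mismatch: "
            f"genotype-only {only_geno}, metadata-only {only_meta}"
        )
    meta = meta.set_index(pd.Index(meta_ids))

    def _opt(row, key, conv=str):
        if key not in row or not str(row[key]).strip():
            return None
        return conv(str(row[key]).strip())

    records = []
    for sid, calls in genotypes.items():
        row = meta.loc[sid]
        obs = _opt(row, "field_obs")
        records.append(SampleRecord(
            sample_id=sid,
            genotype=Genotype(loci_t, calls),
            sex=_opt(row, "sex"),
            mtdna_haplotype=_opt(row, "mtdna_haplotype"),
            body_length_m=_opt(row, "body_length_m", float),
            date=_parse_date(str(row.get("date", "")), config, sid),
            lat=_opt(row, "lat", float),
            lon=_opt(row, "lon", float),
            vessel=_opt(row, "vessel"),
            field_obs=frozenset(obs.split(";")) if obs else frozenset(),
        ))
    return records


def write_samples(samples: Sequence[SampleRecord], genotype_path, metadata_path,
                  config: IOConfig | None = None) -> None:
    """Write canonical tables that :func:`read_samples` round-trips."""
    config = config or IOConfig()
    if config.dialect == "genepop":
        _write_genepop(samples, genotype_path)
    else:
        loci = samples[0].genotype.loci
        rows = []
        for s in samples:
            row = {"sample_id": s.sample_id}
            for locus, call in zip(loci, s.genotype.calls):
                if config.dialect == "wide":
                    row[f"{locus}_1"] = "" if call is None else str(call[0])
                    row[f"{locus}_2"] = "" if call is None else str(call[1])
                else:
                    row[locus] = "" if call is None else f"{call[0]}{config.packed_sep}{call[1]}"
            rows.append(row)
        pd.DataFrame(rows).to_csv(genotype_path, sep=config.sep, index=False)

    meta_rows = []
    for s in samples:
        meta_rows.append({
            "sample_id": s.sample_id,
            "sex": s.sex or "",
            "mtdna_haplotype": s.mtdna_haplotype or "",
            "body_length_m": "" if s.body_length_m is None else f"{s.body_length_m:g}",
            "date": "" if s.date is None else s.date.isoformat(),
            "lat": "" if s.lat is None else f"{s.lat:g}",
            "lon": "" if s.lon is None else f"{s.lon:g}",
            "vessel": s.vessel or "",
            "field_obs": ";".join(sorted(s.field_obs)),
        })
    pd.DataFrame(meta_rows).to_csv(metadata_path, index=False)


def _write_genepop(samples: Sequence[SampleRecord], path) -> None:
    loci = samples[0].genotype.loci
    width = 3
    lines = ["kinlod genotype export"]
    lines.extend(str(l) for l in loci)
    lines.append("POP")
    for s in samples:
        fields = []
        for call in s.genotype.calls:
            if call is None:
                fields.append("0" * (2 * width))
            else:
                fields.append(f"{int(call[0]):0{width}d}{int(call[1]):0{width}d}")
        lines.append(f"{s.sample_id} , " + " ".join(fields))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Allele frequencies and Hardy–Weinberg QC


def estimate_allele_freqs(samples: Sequence[SampleRecord]) -> list:
    """Observed allele-count frequencies per locus.

    Missing loci contribute nothing.  A locus with zero typed alleles is a
    hard error; a monomorphic locus is returned (and flagged by the
    ``LocusModel``) rather than rejected.
    """
    if not samples:
        raise ValueError("no samples")
    loci = samples[0].genotype.loci
    models = []
    for k, locus in enumerate(loci):
        counts: dict = {}
        for s in samples:
            call = s.genotype.calls[k]
            if call is None:
                continue
            for allele in call:
                counts[allele] = counts.get(allele, 0) + 1
        if not counts:
            raise ValueError(f"locus {locus}: zero typed alleles")
        alleles = sorted(counts, key=lambda a: (str(type(a)), a))
        total = sum(counts.values())
        freqs = np.array([counts[a] / total for a in alleles], dtype=float)
        model = LocusModel(str(locus), tuple(alleles), freqs)
        if model.is_monomorphic:
            logger.warning("locus %s is monomorphic", locus)
        models.append(model)
    return models


def hwe_check(samples: Sequence[SampleRecord], locus: LocusModel) -> HWEResult:
    """Chi-square goodness of fit of genotype counts to Hardy–Weinberg.

    Genotype classes with expected count < 5 are pooled into a single rare
    class; df = (#classes after pooling − #alleles), clipped at 1.  A
    monomorphic locus yields a defined non-testable result.
    """
    if locus.is_monomorphic:
        return HWEResult(locus.name, float("nan"), 0, float("nan"), False, "monomorphic")
    loci = samples[0].genotype.loci
    k = list(loci).index(locus.name) if locus.name in map(str, loci) else None
    if k is None:
        raise ValueError(f"locus {locus.name} not present in samples")

    p = locus.freqs
    idx = {a: i for i, a in enumerate(locus.alleles)}
    observed: dict = {}
    n = 0
    for s in samples:
        call = s.genotype.calls[k]
        if call is None:
            continue
        key = (idx[call[0]], idx[call[1]])
        observed[key] = observed.get(key, 0) + 1
        n += 1
    if n == 0:
        return HWEResult(locus.name, float("nan"), 0, float("nan"), False, "no typed samples")

    classes = []
    for i in range(locus.n_alleles):
        for j in range(i, locus.n_alleles):
            expected = n * (p[i] ** 2 if i == j else 2 * p[i] * p[j])
            classes.append((observed.get((i, j), 0), expected))

    kept = [(o, e) for o, e in classes if e >= 5.0]
    pooled = [(o, e) for o, e in classes if e < 5.0]
    if pooled:
        kept.append((sum(o for o, _ in pooled), sum(e for _, e in pooled)))
    stat = sum((o - e) ** 2 / e for o, e in kept if e > 0)
    df = max(len(kept) - locus.n_alleles, 1)
    pvalue = float(stats.chi2.sf(stat, df))
    return HWEResult(locus.name, float(stat), df, pvalue, True)


# ---------------------------------------------------------------------------
# Duplicate / resample detection


def deduplicate(samples: Sequence[SampleRecord], kinship_model_ctx, threshold: float | None = None,
                *, n_sim: int = 20000, seed: int = 0) -> DedupResult:
    """Merge samples that are the same individual biopsied more than once.

    The merge criterion is joint: the self/monozygotic LOD (SELF vs
    unrelated) must exceed ``threshold`` *and* SELF must be the
    maximum-likelihood category among {U, HS, FS, PO, SELF} — a
    parent-offspring pair can clear a permissive self-LOD threshold, but
    its PO likelihood always dominates.  Merging is transitive; the default
    threshold comes from :func:`default_dedup_threshold` on the same model
    context.  Groups whose members share date and position are tagged
    ``same_place_time_duplicate``; otherwise ``resample``.  One record per
    individual is retained — earliest sampling date, ties broken by
    sample-id order.
    """
    from . import kinship_model as km  # deferred: kinship_model imports our types

    needed = {"SELF", "PO", "FS", "HS"}
    if not needed <= set(kinship_model_ctx.hypothesis_labels):
        raise ValueError("deduplicate needs a context with SELF, PO, FS and HS cached")

    samples = list(samples)
    n = len(samples)
    if threshold is None:
        n_pairs = n * (n - 1) // 2
        threshold = default_dedup_threshold(kinship_model_ctx, n_pairs, n_sim=n_sim, seed=seed)

    codes = km.encode_genotypes([s.genotype for s in samples], kinship_model_ctx)
    ii, jj = np.triu_indices(n, 1)
    self_lod = km.pairwise_lod(codes, kinship_model_ctx, "SELF", ii, jj)
    ml_is_self = np.ones(len(ii), dtype=bool)
    for other in ("PO", "FS", "HS", "U"):
        rival = (np.zeros(len(ii)) if other == "U"
                 else km.pairwise_lod(codes, kinship_model_ctx, other, ii, jj))
        ml_is_self &= self_lod > rival  # ties go to the less related category
    self_lod = np.where(ml_is_self, self_lod, -np.inf)

    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in zip(ii[self_lod > threshold], jj[self_lod > threshold]):
        ra, rb = find(int(a)), find(int(b))
        if ra != rb:
            parent[rb] = ra

    groups: dict = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)

    unique, dup_groups = [], []
    for members in groups.values():
        recs = [samples[i] for i in members]
        recs.sort(key=lambda r: (r.date or _dt.date.max, r.sample_id))
        retained = recs[0]
        unique.append(retained)
        if len(recs) > 1:
            same = all(r.date == retained.date and r.lat == retained.lat
                       and r.lon == retained.lon for r in recs[1:])
            kind = "same_place_time_duplicate" if same else "resample"
            dup_groups.append(DuplicateGroup(tuple(r.sample_id for r in recs), kind,
                                             retained.sample_id))
    unique.sort(key=lambda r: r.sample_id)
    return DedupResult(unique, dup_groups, n)


def default_dedup_threshold(ctx, n_pairs: int, *, n_sim: int = 20000, seed: int = 0,
                            expected_fp: float = 0.01) -> float:
    """Self-LOD merge threshold targeting < ``expected_fp`` false merges.

    The target per-pair rate (``expected_fp / n_pairs``, ~1e-6 at study
    scale) sits far below Monte-Carlo resolution, so the unrelated-pair
    SELF-LOD tail is extrapolated with a normal approximation of the
    simulated distribution.  The threshold is clamped below the simulated
    SELF-pair distribution's lower tail so true duplicates are not lost;
    with 14 informative loci the two distributions are separated by tens of
    LOD units and the clamp is inactive.
    """
    from . import lod_calibration as lc

    sim_u = lc.simulate_pairs(ctx, "U", n_sim, seed, scored=("SELF",))
    sim_self = lc.simulate_pairs(ctx, "SELF", max(n_sim // 10, 1000), seed + 1,
                                 scored=("SELF",))
    u_lod = sim_u.lods["SELF"]
    z = stats.norm.ppf(1.0 - expected_fp / max(n_pairs, 1))
    threshold = float(u_lod.mean() + z * u_lod.std())
    self_low = float(np.quantile(sim_self.lods["SELF"], 0.001))
    if threshold >= self_low:
        warnings.warn("self-LOD distributions poorly separated; using midpoint threshold")
        threshold = 0.5 * (float(u_lod.max()) + self_low)
    return threshold
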
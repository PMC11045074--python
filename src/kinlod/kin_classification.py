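"""From pair scores to an annotated close-kin dyad list.

A dyad is an unordered pair whose scored LOD (normally LOD_PO) exceeds the
calibrated cut-off.  Dyads are annotated with maternal-line consistency
from maternally inherited mtDNA haplotypes and genetic sex:

* shared known haplotype, sexes {M, F} → ``MS`` (mother–son compatible);
* shared known haplotype, sexes {F, F} → ``MD`` (mother–daughter compatible);
* shared known haplotype, sexes {M, M} → no maternal label (``none``);
* differing haplotypes → ``none``; any unknown haplotype or sex → ``n/a``.

The label never designates which member is parent and which offspring;
when both body lengths are known the larger individual is flagged as the
presumed mother, purely as a consistency note.  Dyads sharing individuals
form triads (connected components of the dyad graph), and elapsed time
between the two samplings is summarised in floored calendar years.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd

from .genotype_io import SampleRecord
from .kinship_model import PairScore

logger = logging.getLogger(__name__)

__all__ = [
    "Dyad",
    "Triad",
    "select_dyads",
    "annotate_maternal",
    "build_triads",
    "elapsed_time_summary",
]


@dataclass(frozen=True)
class Dyad:
    """One selected close-kin pair with its member metadata snapshots."""

    pair: PairScore
    rec_i: SampleRecord
    rec_j: SampleRecord
    scored_hypothesis: str
    cutoff_passed: float
    ml_category: str | None
    maternal_consistency: str = "n/a"  # "MS" | "MD" | "none" | "n/a"
    presumed_mother_id: str | None = None
    field_confirmed: bool = False
    low_confidence: bool = False

    @property
    def ids(self) -> tuple:
        return (self.pair.id_i, self.pair.id_j)

    @property
    def elapsed_days(self) -> int | None:
        if self.rec_i.date is None or self.rec_j.date is None:
            return None
        return abs((self.rec_i.date - self.rec_j.date).days)


@dataclass(frozen=True)
class Triad:
    """Three or more individuals connected through shared dyad membership."""

    member_ids: tuple
    edges: tuple            # dyad id pairs forming the component
    shared_ids: tuple       # individuals occurring in more than one dyad


def select_dyads(pairscores: Sequence[PairScore], records: Sequence[SampleRecord] | Mapping,
                 scored_hypothesis: str = "PO", cutoff: float = 6.0) -> list:
    """Pairs with ``lod[scored_hypothesis] > cutoff``, sorted by descending LOD.

    FS-classified dyads are retained but flagged low-confidence: with
    markers of this power the full-sibling likelihood overlaps both the PO
    and HS ones, so the evidence for true full siblings is weak.
    """
    by_id = records if isinstance(records, Mapping) else {r.sample_id: r for r in records}
    dyads = []
    for score in pairscores:
        value = score.lod.get(scored_hypothesis)
        if value is None or not value > cutoff:
            continue
        ri, rj = by_id[score.id_i], by_id[score.id_j]
        confirmed = ri.mc_partner() == rj.sample_id or rj.mc_partner() == ri.sample_id
        dyads.append(Dyad(
            pair=score, rec_i=ri, rec_j=rj,
            scored_hypothesis=scored_hypothesis, cutoff_passed=cutoff,
            ml_category=score.ml_category,
            field_confirmed=confirmed,
            low_confidence=score.ml_category == "FS",
        ))
    dyads.sort(key=lambda d: -d.pair.lod[scored_hypothesis])
    return dyads


def annotate_maternal(dyad: Dyad) -> Dyad:
    """Attach the mtDNA/sex maternal-consistency label (MS/MD/none/n-a)."""
    ri, rj = dyad.rec_i, dyad.rec_j
    if ri.mtdna_haplotype is None or rj.mtdna_haplotype is None \
            or ri.sex is None or rj.sex is None:
        label = "n/a"
    elif ri.mtdna_haplotype != rj.mtdna_haplotype:
        label = "none"
    else:
        sexes = {ri.sex, rj.sex}
        if sexes == {"M", "F"}:
            label = "MS"
        elif sexes == {"F"}:
            label = "MD"
        else:  # {M, M}: a shared haplotype carries no mother-offspring signal
            label = "none"

    mother = None
    if label in ("MS", "MD") and ri.body_length_m is not None \
            and rj.body_length_m is not None and ri.body_length_m != rj.body_length_m:
        mother = ri.sample_id if ri.body_length_m > rj.body_length_m else rj.sample_id
    return replace(dyad, maternal_consistency=label, presumed_mother_id=mother)


def build_triads(dyads: Sequence[Dyad]) -> list:
    """Connected components of the dyad graph with three or more members.

    Components of exactly two individuals remain plain dyads and are not
    returned.  Each individual belongs to at most one component.
    """
    graph = nx.Graph()
    for d in dyads:
        graph.add_edge(*d.ids)
    triads = []
    for component in nx.connected_components(graph):
        if len(component) < 3:
            continue
        members = tuple(sorted(component))
        edges = tuple(sorted(tuple(sorted(e)) for e in graph.subgraph(component).edges))
        shared = tuple(sorted(v for v in component if graph.degree(v) > 1))
        triads.append(Triad(members, edges, shared))
    triads.sort(key=lambda t: t.member_ids)
    return triads


def elapsed_time_summary(dyads: Sequence[Dyad]) -> pd.DataFrame:
    """Elapsed time between the two samplings of each dyad.

    Years are the calendar-day difference divided by 365.25 and floored,
    so same-season pairs report 0.  Dyads with a missing date are excluded
    with a warning.
    """
    rows = []
    for d in dyads:
        days = d.elapsed_days
        if days is None:
            logger.warning("dyad %s-%s missing a sampling date; excluded", *d.ids)
            continue
        first, second = sorted(filter(None, (d.rec_i.date, d.rec_j.date)))
        rows.append({
            "id_i": d.pair.id_i, "id_j": d.pair.id_j,
            "ml_category": d.ml_category,
            "first_date": first, "second_date": second,
            "elapsed_days": days,
            "elapsed_years": int(days / 365.25),
        })
    frame = pd.DataFrame(rows, columns=["id_i", "id_j", "ml_category", "first_date",
                                        "second_date", "elapsed_days", "elapsed_years"])
    frame.attrs["max_elapsed_years"] = int(frame.elapsed_years.max()) if len(frame) else None
    return frame
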
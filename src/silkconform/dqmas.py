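"""Double-quantum/single-quantum (DQ-SQ) proton correlation assignment.

In a ¹H DQ-SQ (DQMAS) spectrum a cross-peak between protons A and B appears
at two positions, (SQ = δA, DQ = δA + δB) and (SQ = δB, DQ = δA + δB); a
self-correlation (A, A) gives a single peak on the DQ diagonal at
(δA, 2 δA).  Because the double-quantum coherence is mediated by the
homonuclear dipolar coupling, an observable cross-peak implies the two
protons are close in space (here, within about 4 Å), which is what turns
an assigned intermolecular glycerol–fibroin correlation into a distance
restraint.

Conformation-dependent ¹H shifts make the assignment conformation-specific:
the same Ala amide proton resonates at 8.1 ppm in the random coil, 8.7 ppm
in the β-sheet (silk II) form and 7.6 ppm in the repeated β-turn (silk I*)
form, so a peak list can be decomposed into per-conformation correlation
inventories.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SiteKey",
    "ShiftTable",
    "DQPeak",
    "PredictedPeak",
    "Assignment",
    "DistanceRestraint",
    "predict_correlations",
    "assign_peaklist",
    "tabulate_correlations",
    "extract_glyc_restraints",
    "GLYC_CONFORMATION",
]

#: Conformation tag used for the glycerol (plasticizer) proton sites.
GLYC_CONFORMATION = "glyc"

#: A site is identified by (conformation, site label), e.g.
#: ("silkI*", "Ala HN") or ("glyc", "Glyc OH").
SiteKey = tuple[str, str]


class ShiftTable:
    """Conformation-dependent chemical-shift lookup.

    Wraps a table with columns ``conformation``, ``site``, ``shift_ppm``
    (and optionally ``nucleus``).  (conformation, site) pairs are unique.
    """

    def __init__(self, table: pd.DataFrame, nucleus: str = "1H"):
        required = {"conformation", "site", "shift_ppm"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"shift table missing columns: {sorted(missing)}")
        if table.duplicated(["conformation", "site"]).any():
            raise ValueError("duplicate (conformation, site) rows in shift table")
        if not np.isfinite(table["shift_ppm"]).all():
            raise ValueError("non-finite shift in shift table")
        self.table = table.reset_index(drop=True)
        self.nucleus = nucleus
        self._lookup = {
            (row.conformation, row.site): float(row.shift_ppm)
            for row in table.itertuples()
        }

    @classmethod
    def from_csv(cls, path, nucleus: str = "1H") -> "ShiftTable":
        return cls(pd.read_csv(path), nucleus=nucleus)

    def shift(self, conformation: str, site: str) -> float:
        """Chemical shift (ppm) of a site; raises KeyError naming the site."""
        try:
            return self._lookup[(conformation, site)]
        except KeyError:
            raise KeyError(
                f"unknown site ({conformation!r}, {site!r}) in shift table"
            ) from None

    def __contains__(self, key: SiteKey) -> bool:
        return tuple(key) in self._lookup

    def sites(self, conformation: str) -> list[str]:
        sub = self.table[self.table["conformation"] == conformation]
        return list(sub["site"])

    def conformations(self) -> list[str]:
        return list(dict.fromkeys(self.table["conformation"]))

    def __len__(self) -> int:
        return len(self.table)


@dataclass(frozen=True)
class DQPeak:
    """A single 2D cross-peak: single-quantum and double-quantum ppm."""

    sq: float
    dq: float
    intensity: float = 1.0

    def __post_init__(self):
        if not (np.isfinite(self.sq) and np.isfinite(self.dq)):
            raise ValueError("DQPeak coordinates must be finite")


@dataclass(frozen=True)
class PredictedPeak:
    """A predicted peak position together with the generating site pair."""

    sq: float
    dq: float
    pair: tuple[SiteKey, SiteKey]


@dataclass
class Assignment:
    """An accepted site-pair assignment.

    One (A, B) pair with A != B matches two peaks; an (A, A)
    self-correlation matches one.  `deviation` is the largest Euclidean
    (SQ, DQ) distance between a matched peak and its predicted position;
    `ambiguity` lists alternative pairs that also fell within tolerance,
    sorted by increasing deviation.
    """

    pair: tuple[SiteKey, SiteKey]
    peaks: list[DQPeak]
    deviation: float
    ambiguity: list[tuple[SiteKey, SiteKey]] = field(default_factory=list)

    @property
    def site_a(self) -> SiteKey:
        return self.pair[0]

    @property
    def site_b(self) -> SiteKey:
        return self.pair[1]


@dataclass(frozen=True)
class DistanceRestraint:
    """Upper bound on the distance between two proton groups (Å)."""

    group_a: str
    group_b: str
    upper_bound: float = 4.0

    def __post_init__(self):
        if not self.upper_bound > 0:
            raise ValueError("upper_bound must be positive")
        if self.group_a == self.group_b:
            raise ValueError("restraint groups must differ")


def _canonical_pair(a: SiteKey, b: SiteKey) -> tuple[SiteKey, SiteKey]:
    a, b = tuple(a), tuple(b)
    return (a, b) if a <= b else (b, a)


def predict_correlations(
    table: ShiftTable, pairs: list[tuple[SiteKey, SiteKey]]
) -> list[PredictedPeak]:
    """Predicted DQ-SQ peak positions for a list of site pairs.

    A pair (A, B) with distinct shifts yields positions (δA, δA+δB) and
    (δB, δA+δB); a self-pair yields (δA, 2 δA).  The DQ coordinate is the
    sum of the two single-quantum shifts (standard DQ-SQ convention).
    """
    out: list[PredictedPeak] = []
    for a, b in pairs:
        da = table.shift(*a)
        db = table.shift(*b)
        pair = _canonical_pair(a, b)
        dq = da + db
        out.append(PredictedPeak(sq=da, dq=dq, pair=pair))
        if tuple(a) != tuple(b):
            out.append(PredictedPeak(sq=db, dq=dq, pair=pair))
    return out


def default_pair_universe(table: ShiftTable) -> list[tuple[SiteKey, SiteKey]]:
    """All within-conformation site pairs plus glycerol x fibroin cross pairs.

    Within each conformation, all unordered pairs (including self-pairs) of
    its sites; across molecules, every glycerol site paired with every
    fibroin site of every conformation.
    """
    pairs: list[tuple[SiteKey, SiteKey]] = []
    confs = table.conformations()
    for conf in confs:
        keys = [(conf, s) for s in table.sites(conf)]
        pairs.extend(
            _canonical_pair(a, b)
            for a, b in itertools.combinations_with_replacement(keys, 2)
        )
    glyc_keys = [(GLYC_CONFORMATION, s) for s in table.sites(GLYC_CONFORMATION)]
    for conf in confs:
        if conf == GLYC_CONFORMATION:
            continue
        for g in glyc_keys:
            for s in table.sites(conf):
                pairs.append(_canonical_pair(g, (conf, s)))
    return list(dict.fromkeys(pairs))


def assign_peaklist(
    peaks: list[DQPeak],
    table: ShiftTable,
    candidate_pairs: list[tuple[SiteKey, SiteKey]] | None = None,
    tolerance: float = 0.15,
) -> tuple[list[Assignment], list[DQPeak]]:
    """Match observed peaks to candidate site pairs by nearest position.

    Each peak is assigned to the candidate position minimizing the
    Euclidean (SQ, DQ) deviation and accepted iff that deviation is at most
    `tolerance` (ppm).  Peaks within tolerance of several pairs carry the
    alternatives in the resulting assignment's ambiguity list.  Ties in
    deviation are broken by lexicographic pair label, making the assignment
    deterministic.

    Returns (assignments sorted by pair label, unassigned peaks).
    """
    if not tolerance > 0:
        raise ValueError("tolerance must be positive (ppm)")
    if candidate_pairs is None:
        candidate_pairs = default_pair_universe(table)
    predicted = predict_correlations(table, candidate_pairs)
    matched: dict[tuple[SiteKey, SiteKey], Assignment] = {}
    unassigned: list[DQPeak] = []
    for peak in peaks:
        hits = []
        for pos in predicted:
            dev = float(np.hypot(peak.sq - pos.sq, peak.dq - pos.dq))
            if dev <= tolerance:
                hits.append((dev, pos.pair))
        if not hits:
            unassigned.append(peak)
            continue
        hits.sort(key=lambda h: (h[0], h[1]))
        dev, pair = hits[0]
        alts = list(dict.fromkeys(p for _, p in hits[1:] if p != pair))
        if pair in matched:
            asn = matched[pair]
            asn.peaks.append(peak)
            asn.deviation = max(asn.deviation, dev)
            asn.ambiguity = sorted(set(asn.ambiguity) | set(alts))
        else:
            matched[pair] = Assignment(
                pair=pair, peaks=[peak], deviation=dev, ambiguity=sorted(alts)
            )
    assignments = [matched[k] for k in sorted(matched)]
    return assignments, unassigned


def _pair_block(pair: tuple[SiteKey, SiteKey]) -> str:
    """Conformation block a pair belongs to, e.g. 'silkI*' or 'glyc-silkI*'."""
    (conf_a, _), (conf_b, _) = pair
    if conf_a == conf_b:
        return conf_a
    confs = sorted({conf_a, conf_b})
    if GLYC_CONFORMATION in confs:
        other = [c for c in confs if c != GLYC_CONFORMATION][0]
        return f"{GLYC_CONFORMATION}-{other}"
    return "-".join(confs)


def tabulate_correlations(assignments: list[Assignment]) -> pd.Series:
    """Count distinct accepted site pairs per conformation block.

    Duplicated pairs collapse to one, mirroring how a correlation inventory
    counts distinct broken-line connectivities rather than individual peaks.
    """
    pairs = {a.pair for a in assignments}
    counts: dict[str, int] = {}
    for pair in pairs:
        block = _pair_block(pair)
        counts[block] = counts.get(block, 0) + 1
    return pd.Series(counts, dtype=int).sort_index()


def extract_glyc_restraints(
    assignments: list[Assignment], upper_bound: float = 4.0
) -> list[DistanceRestraint]:
    """Turn intermolecular glycerol-fibroin assignments into restraints.

    One restraint per distinct (glycerol site, fibroin site) pair among the
    accepted assignments; intra-fibroin and intra-glycerol pairs are
    excluded; duplicates collapse.  The default 4 Å bound is the nominal
    detection range of the DQ-SQ experiment.
    """
    if not upper_bound > 0:
        raise ValueError("upper_bound must be positive")
    seen: dict[tuple[str, str], DistanceRestraint] = {}
    for asn in assignments:
        (conf_a, site_a), (conf_b, site_b) = asn.pair
        a_glyc = conf_a == GLYC_CONFORMATION
        b_glyc = conf_b == GLYC_CONFORMATION
        if a_glyc == b_glyc:  # intra-molecular: both glyc or both SF
            continue
        glyc_site, sf_site = (site_a, site_b) if a_glyc else (site_b, site_a)
        key = (glyc_site, sf_site)
        if key not in seen:
            seen[key] = DistanceRestraint(
                group_a=glyc_site, group_b=sf_site, upper_bound=upper_bound
            )
    return [seen[k] for k in sorted(seen)]
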
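"""Prey volume, the diet-composition table, IRI ranking, and size summaries.

The quantitative core of stomach-content diet analysis:

* each prey item's volume is estimated from its maximum length ``L`` and
  width ``W`` with the prolate-spheroid formula

  .. math:: V = \\frac{4\\pi}{3}\\,\\frac{L}{2}\\left(\\frac{W}{2}\\right)^2

* per prey category, the table tallies the frequency of occurrence ``F``
  (stomachs containing the category), abundance ``N`` (items) and total
  volume ``V`` (mm^3), converts each to a percentage of its column total,
  and scores importance with the index of relative importance

  .. math:: \\mathrm{IRI} = (\\%F + \\%N + \\%V)/3

Percentages are computed unrounded; presentation rounds half away from
zero to 2 decimals, under which each percentage column and the IRI column
sum to 100 up to rounding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .data import Dataset, GeckodietError, PreyItem

__all__ = [
    "PI_PAPER",
    "prey_volume",
    "compute_volumes",
    "CompositionRow",
    "CompositionTable",
    "composition_table",
    "composition_from_aggregates",
    "rank_by_iri",
    "SizeSummary",
    "size_summary",
    "trophic_spectrum",
    "round_half_away",
]

#: Truncated value of pi used by a widely followed field protocol for the
#: spheroid volume; selectable for exact reproduction of published tables.
PI_PAPER = 3.14

_PI = {"exact": math.pi, "paper_3_14": PI_PAPER}


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (the convention of published diet tables)."""
    factor = 10.0 ** ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


def prey_volume(length_mm, width_mm, pi_mode: str = "exact"):
    """Prolate-spheroid volume of a prey item, mm^3.

    ``V = (4*pi/3) * (L/2) * (W/2)**2``; strictly increasing in both
    dimensions.  Accepts scalars or numpy arrays.  ``pi_mode`` is
    ``"exact"`` (full-precision pi) or ``"paper_3_14"`` (pi = 3.14).
    """
    if pi_mode not in _PI:
        raise ValueError(f"pi_mode must be one of {sorted(_PI)}, got {pi_mode!r}")
    length = np.asarray(length_mm, dtype=float)
    width = np.asarray(width_mm, dtype=float)
    if np.any(length <= 0) or np.any(width <= 0):
        raise GeckodietError("prey dimensions must be strictly positive")
    vol = (4.0 * _PI[pi_mode] / 3.0) * (length / 2.0) * (width / 2.0) ** 2
    return float(vol) if np.isscalar(length_mm) and np.isscalar(width_mm) else vol


def compute_volumes(dataset: Dataset, pi_mode: str = "exact") -> Dataset:
    """Return a copy of the dataset with every prey item's volume filled in."""
    items = tuple(
        PreyItem(
            specimen_id=p.specimen_id,
            category=p.category,
            taxon_class=p.taxon_class,
            length_mm=p.length_mm,
            width_mm=p.width_mm,
            volume_mm3=prey_volume(p.length_mm, p.width_mm, pi_mode),
        )
        for p in dataset.prey_items
    )
    return Dataset(dataset.specimens, items)


@dataclass(frozen=True)
class CompositionRow:
    """One prey category's tallies and percentages (a published-table row)."""

    category: str
    F: int
    pctF: float
    N: int
    pctN: float
    V: float
    pctV: float
    iri: float
    taxon_class: str | None = None


@dataclass(frozen=True)
class CompositionTable:
    """The full diet-composition table.

    ``rows`` hold unrounded percentages; :meth:`to_frame` with
    ``rounded=True`` applies the 2-decimal presentation convention.
    """

    rows: tuple[CompositionRow, ...]
    total_F: int
    total_N: int
    total_V: float
    n_stomachs: int
    freq_denominator: str

    def __post_init__(self):
        object.__setattr__(self, "rows", tuple(self.rows))

    def row(self, category: str) -> CompositionRow:
        for r in self.rows:
            if r.category == category:
                return r
        raise KeyError(category)

    @property
    def categories(self) -> tuple[str, ...]:
        return tuple(r.category for r in self.rows)

    def to_frame(self, rounded: bool = False) -> pd.DataFrame:
        """Table as a DataFrame in the published column order."""
        df = pd.DataFrame(
            [
                (r.category, r.taxon_class, r.F, r.pctF, r.N, r.pctN, r.V, r.pctV,
                 r.iri)
                for r in self.rows
            ],
            columns=["category", "taxon_class", "F", "pctF", "N", "pctN", "V",
                     "pctV", "iri"],
        )
        if rounded:
            for col in ("pctF", "pctN", "pctV", "iri"):
                df[col] = df[col].map(lambda v: round_half_away(v, 2))
            df["V"] = df["V"].map(lambda v: round_half_away(v, 2))
        return df


def _as_group_filter(group_filter) -> Callable[[object], bool] | None:
    if group_filter is None or callable(group_filter):
        return group_filter
    if isinstance(group_filter, str):
        return lambda s: s.group == group_filter
    groups = set(group_filter)
    return lambda s: s.group in groups


def composition_table(
    dataset: Dataset,
    group_filter=None,
    freq_denominator: str = "sum_of_F",
    pi_mode: str = "exact",
    sort_by: str | None = None,
) -> CompositionTable:
    """Tally the diet-composition table from a dataset.

    Parameters
    ----------
    dataset : specimens and prey items; volumes are computed on the fly
        from L and W when absent.
    group_filter : optional group label, iterable of labels, or predicate
        on :class:`~geckodiet.data.Specimen`.
    freq_denominator : ``"sum_of_F"`` divides %F by the summed occurrences
        across categories (the convention that reproduces published gecko
        diet tables); ``"n_stomachs"`` divides by the number of stomachs,
        the commoner convention in the diet literature (then %F does not
        sum to 100).
    sort_by : optional column to sort rows by, descending for numeric
        columns (default: first-appearance order of categories).
    """
    if freq_denominator not in ("sum_of_F", "n_stomachs"):
        raise ValueError(f"unknown freq_denominator {freq_denominator!r}")
    pred = _as_group_filter(group_filter)
    specimens = dataset.specimens if pred is None else tuple(
        s for s in dataset.specimens if pred(s)
    )
    ids = {s.specimen_id for s in specimens}
    items = [p for p in dataset.prey_items if p.specimen_id in ids]
    if not specimens or not items:
        raise GeckodietError("no prey items to tabulate after filtering")

    tallies: dict[str, dict] = {}
    for p in items:
        volume = p.volume_mm3
        if volume is None:
            volume = prey_volume(p.length_mm, p.width_mm, pi_mode)
        t = tallies.setdefault(
            p.category,
            {"stomachs": set(), "N": 0, "V": 0.0, "taxon_class": p.taxon_class},
        )
        t["stomachs"].add(p.specimen_id)
        t["N"] += 1
        t["V"] += volume

    records = [
        (cat, t["taxon_class"], len(t["stomachs"]), t["N"], t["V"])
        for cat, t in tallies.items()
    ]
    return _percentages(records, n_stomachs=len(specimens),
                        freq_denominator=freq_denominator, sort_by=sort_by)


def composition_from_aggregates(
    counts,
    n_stomachs: int | None = None,
    freq_denominator: str = "sum_of_F",
    sort_by: str | None = None,
) -> CompositionTable:
    """Build the composition table from already-tallied per-category counts.

    ``counts`` is a DataFrame with columns ``category, F, N, V`` (and
    optionally ``taxon_class``), or an iterable of ``(category, F, N, V)``
    tuples — e.g. the printed counts of a published diet table, from which
    the percentage and IRI columns are recomputed.
    """
    if isinstance(counts, pd.DataFrame):
        df = counts
        taxa = df["taxon_class"] if "taxon_class" in df else [None] * len(df)
        records = list(zip(df["category"], taxa, df["F"].astype(int),
                           df["N"].astype(int), df["V"].astype(float)))
    else:
        records = [(c, None, int(f), int(n), float(v)) for c, f, n, v in counts]
    if not records:
        raise GeckodietError("no categories to tabulate")
    return _percentages(records, n_stomachs=n_stomachs,
                        freq_denominator=freq_denominator, sort_by=sort_by)


def _percentages(records, n_stomachs, freq_denominator, sort_by) -> CompositionTable:
    total_F = sum(r[2] for r in records)
    total_N = sum(r[3] for r in records)
    total_V = sum(r[4] for r in records)
    if total_V <= 0:
        raise GeckodietError("total prey volume is zero; cannot form percentages")
    denom_F = total_F if freq_denominator == "sum_of_F" else n_stomachs
    if not denom_F:
        raise GeckodietError(
            "freq_denominator='n_stomachs' requires a known stomach count"
        )
    rows = []
    for cat, taxon, F, N, V in records:
        if N >= 1 and F < 1:
            raise GeckodietError(f"category {cat!r}: N >= 1 requires F >= 1")
        pctF = 100.0 * F / denom_F
        pctN = 100.0 * N / total_N
        pctV = 100.0 * V / total_V
        rows.append(CompositionRow(
            category=cat, taxon_class=taxon, F=F, pctF=pctF, N=N, pctN=pctN,
            V=V, pctV=pctV, iri=(pctF + pctN + pctV) / 3.0,
        ))
    if sort_by is not None:
        if sort_by == "category":
            rows.sort(key=lambda r: r.category)
        else:
            rows.sort(key=lambda r: (-getattr(r, sort_by), r.category))
    return CompositionTable(
        rows=tuple(rows), total_F=total_F, total_N=total_N, total_V=total_V,
        n_stomachs=n_stomachs if n_stomachs is not None else total_F,
        freq_denominator=freq_denominator,
    )


def rank_by_iri(
    table: CompositionTable,
    top_k: int | None = None,
    min_stomachs: int = 1,
) -> list[str]:
    """Categories ordered by non-increasing IRI.

    Ties break by descending N, then lexicographic category.
    ``min_stomachs`` drops categories found in fewer stomachs before
    ranking — published "most important prey" narratives typically skip
    single-stomach categories even when a large single item gives them a
    sizeable IRI; ``min_stomachs=2`` reproduces that reading.
    """
    rows = [r for r in table.rows if r.F >= min_stomachs]
    rows.sort(key=lambda r: (-r.iri, -r.N, r.category))
    cats = [r.category for r in rows]
    return cats[:top_k] if top_k is not None else cats


@dataclass(frozen=True)
class SizeSummary:
    """Descriptive statistics of one prey dimension or per-stomach aggregate."""

    n: int
    mean: float
    sd: float
    min: float
    max: float
    median: float

    def __str__(self):
        return (f"{self.mean:.2f} ± {self.sd:.2f} "
                f"(min–max: {self.min:.2f}–{self.max:.2f}, n = {self.n})")


_DIMENSIONS = ("length", "width", "volume", "count_per_stomach",
               "total_volume_per_stomach")


def size_summary(
    dataset: Dataset,
    dimension: str = "length",
    group_filter=None,
    pi_mode: str = "exact",
    include_empty_stomachs: bool = False,
) -> SizeSummary:
    """Mean, sample SD (n-1), min, max and median of a prey-size dimension.

    ``dimension`` is one of ``length``, ``width``, ``volume`` (per item),
    or ``count_per_stomach`` / ``total_volume_per_stomach`` (aggregated
    per specimen first).  Specimens with no recovered items are excluded
    from per-stomach summaries unless ``include_empty_stomachs``.
    A single observation reports sd = 0.
    """
    if dimension not in _DIMENSIONS:
        raise ValueError(f"dimension must be one of {_DIMENSIONS}, got {dimension!r}")
    pred = _as_group_filter(group_filter)
    specimens = dataset.specimens if pred is None else tuple(
        s for s in dataset.specimens if pred(s)
    )
    ids = {s.specimen_id for s in specimens}
    items = [p for p in dataset.prey_items if p.specimen_id in ids]

    if dimension == "length":
        values = np.array([p.length_mm for p in items])
    elif dimension == "width":
        values = np.array([p.width_mm for p in items])
    elif dimension == "volume":
        values = np.array([
            p.volume_mm3 if p.volume_mm3 is not None
            else prey_volume(p.length_mm, p.width_mm, pi_mode)
            for p in items
        ])
    else:
        per: dict[str, float] = {i: 0.0 for i in ids} if include_empty_stomachs else {}
        for p in items:
            if dimension == "count_per_stomach":
                per[p.specimen_id] = per.get(p.specimen_id, 0.0) + 1.0
            else:
                v = (p.volume_mm3 if p.volume_mm3 is not None
                     else prey_volume(p.length_mm, p.width_mm, pi_mode))
                per[p.specimen_id] = per.get(p.specimen_id, 0.0) + v
        values = np.array(list(per.values()))

    if values.size == 0:
        raise GeckodietError(f"no observations for dimension {dimension!r}")
    sd = float(np.std(values, ddof=1)) if values.size > 1 else 0.0
    return SizeSummary(
        n=int(values.size), mean=float(np.mean(values)), sd=sd,
        min=float(np.min(values)), max=float(np.max(values)),
        median=float(np.median(values)),
    )


def trophic_spectrum(dataset: Dataset, by: str | None = "group") -> dict:
    """Number of distinct prey categories consumed, overall or per group.

    With ``by="group"`` returns ``{group: count}`` over groups present in
    the specimen table (0 for groups whose specimens ate nothing); with
    ``by=None`` returns the single overall count.
    """
    if by is None:
        return {"all": len({p.category for p in dataset.prey_items})}
    group_of = {s.specimen_id: s.group for s in dataset.specimens}
    cats: dict[str, set] = {s.group: set() for s in dataset.specimens}
    for p in dataset.prey_items:
        cats[group_of[p.specimen_id]].add(p.category)
    return {g: len(c) for g, c in cats.items()}
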
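"""Indicator definitions and cluster-level record assembly.

Households report a water-source and sanitation-facility category; these are
classified into the coverage indicators used throughout the package:

* ``improved_water`` — source protected from outside (especially faecal)
  contamination: piped supplies, public taps, tube/bore wells, protected
  wells and springs, rainwater.
* ``improved_sanitation`` — facility that hygienically separates excreta
  from human contact: flush/sewer/septic systems, VIP latrines, pit
  latrines with a slab, composting toilets. Sharing a facility does NOT
  demote it here; pit latrines whose slab status is unknown (older survey
  codings) are counted unimproved to avoid misclassification.
* ``open_defecation`` — no facility / bush / field.
* ``accessible_improved_water`` — improved AND within 1 km or 15 minutes.
* ``private_improved_sanitation`` — improved AND not shared.

Classification is a pure function of the normalized category string plus the
stated modifiers, backed by a packaged vocabulary (data, not code) that can
be extended with survey-specific synonyms.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .hierarchy import AdminHierarchy

logger = logging.getLogger(__name__)

__all__ = [
    "SurveySiteRecord",
    "Vocabulary",
    "classify_water_source",
    "classify_sanitation",
    "aggregate_to_sites",
    "allocate_admin1_only",
    "INDICATORS",
]

#: indicators modelled spatially (the reduced-availability accessible/private
#: variants are summarized nationally only)
INDICATORS = ("improved_water", "improved_sanitation", "open_defecation")


@dataclass
class SurveySiteRecord:
    """One survey cluster: location, stratum, year and binomial counts.

    ``k`` maps indicator name → households positive; ``n`` maps indicator
    name → households with a non-missing response. ``weight`` is 1 unless
    the record arose from spreading an admin1-only site over its admin2.
    """

    country: str
    admin1: str
    admin2: str | None
    urban: bool
    year: int
    n: dict[str, int]
    k: dict[str, int]
    weight: float = 1.0
    site_id: str | None = None

    def __post_init__(self) -> None:
        for ind, kk in self.k.items():
            nn = self.n.get(ind, 0)
            if not (0 <= kk <= nn):
                raise ValueError(
                    f"site {self.site_id!r}: k={kk} outside [0, n={nn}] for {ind}"
                )
        if not (0 < self.weight <= 1):
            raise ValueError(f"weight {self.weight} outside (0, 1]")


def _normalize(text: str) -> str:
    return re.sub(r"\s+", " ", text.strip().lower())


@dataclass
class Vocabulary:
    """Category lists defining the indicators, with synonym support."""

    improved_water: set[str]
    improved_sanitation: set[str]
    open_defecation: set[str]
    ambiguous_pit_latrine: set[str]
    water_synonyms: dict[str, str] = field(default_factory=dict)
    sanitation_synonyms: dict[str, str] = field(default_factory=dict)

    @classmethod
    def load(cls, path: str | Path | None = None,
             extra_synonyms: Mapping[str, str] | None = None) -> "Vocabulary":
        if path is None:
            text = resources.files("wssmap").joinpath("data/categories.yaml").read_text()
        else:
            text = Path(path).read_text()
        raw = yaml.safe_load(text)
        vocab = cls(
            improved_water={_normalize(c) for c in raw["improved_water"]},
            improved_sanitation={_normalize(c) for c in raw["improved_sanitation"]},
            open_defecation={_normalize(c) for c in raw["open_defecation"]},
            ambiguous_pit_latrine={_normalize(c) for c in raw.get("ambiguous_pit_latrine", [])},
            water_synonyms={_normalize(k): _normalize(v)
                            for k, v in raw.get("water_synonyms", {}).items()},
            sanitation_synonyms={_normalize(k): _normalize(v)
                                 for k, v in raw.get("sanitation_synonyms", {}).items()},
        )
        if extra_synonyms:
            for k, v in extra_synonyms.items():
                vocab.water_synonyms[_normalize(k)] = _normalize(v)
                vocab.sanitation_synonyms[_normalize(k)] = _normalize(v)
        return vocab


_DEFAULT_VOCAB: Vocabulary | None = None


def _vocab(vocab: Vocabulary | None) -> Vocabulary:
    global _DEFAULT_VOCAB
    if vocab is not None:
        return vocab
    if _DEFAULT_VOCAB is None:
        _DEFAULT_VOCAB = Vocabulary.load()
    return _DEFAULT_VOCAB


def classify_water_source(
    category: str,
    time_minutes: float | None = None,
    distance_km: float | None = None,
    *,
    vocab: Vocabulary | None = None,
    time_threshold_minutes: float = 15.0,
    distance_threshold_km: float = 1.0,
) -> dict[str, bool | None]:
    """Classify a water-source category.

    Returns ``{"improved": bool, "accessible_improved": bool | None}``;
    the accessible flag is ``None`` when neither a distance nor a time to
    the source was supplied. Unknown categories classify as unimproved
    (and are logged).
    """
    if not category or not category.strip():
        raise ValueError("empty water-source category")
    v = _vocab(vocab)
    cat = _normalize(category)
    cat = v.water_synonyms.get(cat, cat)
    improved = cat in v.improved_water
    if not improved and cat not in v.improved_water:
        if cat not in v.open_defecation:  # unknown, not just unimproved-by-list
            logger.debug("water category %r not in improved list; unimproved", category)
    if time_minutes is None and distance_km is None:
        accessible: bool | None = None
    else:
        near = False
        if distance_km is not None and distance_km <= distance_threshold_km:
            near = True
        if time_minutes is not None and time_minutes <= time_threshold_minutes:
            near = True
        accessible = improved and near
    return {"improved": improved, "accessible_improved": accessible}


def classify_sanitation(
    category: str,
    shared: bool | None = None,
    slab_known: bool = True,
    *,
    vocab: Vocabulary | None = None,
) -> dict[str, bool | None]:
    """Classify a sanitation-facility category.

    Returns ``improved``, ``open_defecation`` and ``private_improved``
    flags. Sharing never demotes the main indicator; ``private_improved``
    is ``None`` when sharing status is unknown. Pit latrines whose slab
    status is unknown count as unimproved.
    """
    if not category or not category.strip():
        raise ValueError("empty sanitation category")
    v = _vocab(vocab)
    cat = _normalize(category)
    cat = v.sanitation_synonyms.get(cat, cat)
    od = cat in v.open_defecation
    if cat in v.ambiguous_pit_latrine:
        improved = False
    elif cat == "pit latrine with slab" and not slab_known:
        improved = False
    else:
        improved = cat in v.improved_sanitation
    if shared is None:
        private: bool | None = None
    else:
        private = improved and not shared
    return {"improved": improved, "open_defecation": od, "private_improved": private}


def aggregate_to_sites(
    households: pd.DataFrame,
    indicator_columns: Sequence[str] = INDICATORS,
) -> list[SurveySiteRecord]:
    """Collapse household rows to cluster-level binomial records.

    ``households`` needs columns ``site_id, country, admin1, admin2, urban,
    year`` plus one boolean (nullable) column per indicator. Per site and
    indicator, ``n`` counts non-missing responses and ``k`` positives;
    indicators with no responses at a site carry ``n = 0``. A site whose
    location fields are inconsistent across rows raises; an entirely empty
    site yields no record (with a warning).
    """
    records: list[SurveySiteRecord] = []
    loc_cols = ["country", "admin1", "admin2", "urban", "year"]
    for site_id, grp in households.groupby("site_id", sort=True):
        locs = grp[loc_cols].drop_duplicates()
        if len(locs) > 1:
            raise ValueError(f"site {site_id!r} has inconsistent location fields")
        loc = locs.iloc[0]
        n: dict[str, int] = {}
        k: dict[str, int] = {}
        for ind in indicator_columns:
            col = grp[ind]
            non_missing = col.notna()
            n[ind] = int(non_missing.sum())
            k[ind] = int(col[non_missing].astype(bool).sum())
        if all(v == 0 for v in n.values()):
            logger.warning("site %r has no responses for any indicator; dropped", site_id)
            continue
        admin2 = loc["admin2"]
        records.append(
            SurveySiteRecord(
                country=str(loc["country"]),
                admin1=str(loc["admin1"]),
                admin2=None if pd.isna(admin2) else str(admin2),
                urban=bool(loc["urban"]),
                year=int(loc["year"]),
                n=n,
                k=k,
                site_id=str(site_id),
            )
        )
    return records


def allocate_admin1_only(
    records: Iterable[SurveySiteRecord], hierarchy: AdminHierarchy
) -> list[SurveySiteRecord]:
    """Spread admin1-only records over the admin2 of their admin1.

    A record with unknown admin2 is replaced by one copy per admin2 in its
    admin1, each carrying weight ``1/m`` (m = number of admin2), so total
    weight is conserved. Located records pass through unchanged.
    """
    out: list[SurveySiteRecord] = []
    for rec in records:
        if rec.admin2 is not None:
            out.append(rec)
            continue
        members = hierarchy.admin2_in_admin1(rec.admin1)
        if not members:
            raise ValueError(f"admin1 {rec.admin1!r} contains no admin2")
        w = rec.weight / len(members)
        for a2 in members:
            out.append(replace(rec, admin2=a2, weight=w))
    return out


# -- CSV I/O for the canonical site table ---------------------------------

_SITE_COLUMNS = [
    "country", "admin1", "admin2", "urban", "year", "n_households",
    "k_improved_water", "k_improved_sanitation", "k_open_defecation", "weight",
]


def records_to_frame(records: Iterable[SurveySiteRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        # canonical table assumes a common n across the three main indicators
        n_vals = {r.n.get(i, 0) for i in INDICATORS}
        n = max(n_vals)
        rows.append(
            {
                "country": r.country,
                "admin1": r.admin1,
                "admin2": "" if r.admin2 is None else r.admin2,
                "urban": int(r.urban),
                "year": r.year,
                "n_households": n,
                "k_improved_water": r.k.get("improved_water", 0),
                "k_improved_sanitation": r.k.get("improved_sanitation", 0),
                "k_open_defecation": r.k.get("open_defecation", 0),
                "weight": r.weight,
            }
        )
    return pd.DataFrame(rows, columns=_SITE_COLUMNS)


def write_sites_csv(records: Iterable[SurveySiteRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def read_sites_csv(path: str | Path) -> list[SurveySiteRecord]:
    df = pd.read_csv(path, keep_default_na=False, na_values=[])
    records = []
    for i, row in df.iterrows():
        n = int(row["n_households"])
        admin2 = str(row["admin2"])
        records.append(
            SurveySiteRecord(
                country=str(row["country"]),
                admin1=str(row["admin1"]),
                admin2=admin2 if admin2 else None,
                urban=bool(int(row["urban"])),
                year=int(row["year"]),
                n={ind: n for ind in INDICATORS},
                k={
                    "improved_water": int(row["k_improved_water"]),
                    "improved_sanitation": int(row["k_improved_sanitation"]),
                    "open_defecation": int(row["k_open_defecation"]),
                },
                weight=float(row["weight"]),
                site_id=f"row{i}",
            )
        )
    return records
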
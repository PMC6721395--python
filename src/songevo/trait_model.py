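"""Species-level trait model: learning-window codings, study aggregation,
trait transforms, and mating-behavior classification.

The learning window of each species is coded three ways:

* binary: ``stable`` (song crystallizes by the end of the first breeding
  season) vs ``plastic`` (syllable repertoire still changes afterwards);
* ternary: ``early`` (stabilizes before the first breeding season),
  ``delayed`` (during it), ``plastic``;
* continuous years in [0, 2]: the reported stabilization age for early
  species, 1.33 (end of the first breeding season) for delayed species,
  and 2.0 for plastic species.

Species that delay plumage maturation past the first breeding season are
an exception: they are coded binary-stable but receive years = 2.0.

Seven song traits are carried per species as lists of per-study raw
values; analyses aggregate them (median by default, min/max for
robustness runs) and work on the natural-log scale.  Two traits are
derived: rate = 60 / (duration + interval) songs per minute, and
continuity = duration / (duration + interval).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .phylo_core import Phylogeny, prune_to_taxa

__all__ = [
    "SpeciesRecord",
    "AnalysisDataset",
    "SONG_TRAITS",
    "RAW_TRAITS",
    "code_learning_window",
    "aggregate_trait",
    "derive_song_metrics",
    "impute_syllable_repertoire",
    "classify_mating",
    "binarize_by_threshold",
    "build_analysis_dataset",
    "records_to_csv",
    "records_from_csv",
]

RAW_TRAITS = (
    "syllable_repertoire",
    "song_repertoire",
    "syllables_per_song",
    "duration_s",
    "interval_s",
)
SONG_TRAITS = RAW_TRAITS + ("rate_per_min", "continuity")

DELAYED_YEARS = 1.33  # end of the first breeding season
PLASTIC_YEARS = 2.0
POLYGYNY_THRESHOLD = 0.05  # >= 5% of males with more than one social mate
EPP_THRESHOLD = 0.10  # >= 10% extra-pair young or nests


class TraitValidationError(ValueError):
    pass


@dataclass
class SpeciesRecord:
    """One species' codings and per-study raw song-trait values."""

    species: str
    family: str
    learning_binary: str  # 'stable' | 'plastic'
    learning_ternary: str | None = None  # 'early' | 'delayed' | 'plastic'
    learning_years: float | None = None
    syllable_repertoire: list[float] = field(default_factory=list)
    song_repertoire: list[float] = field(default_factory=list)
    syllables_per_song: list[float] = field(default_factory=list)
    duration_s: list[float] = field(default_factory=list)
    interval_s: list[float] = field(default_factory=list)
    polygynous_male_fraction: float | None = None
    epp_fraction: float | None = None
    imputed_syllable_repertoire: bool = False

    def validate(self) -> None:
        if self.learning_binary not in ("stable", "plastic"):
            raise TraitValidationError(
                f"{self.species}: learning_binary {self.learning_binary!r}"
            )
        if self.learning_ternary is not None:
            if self.learning_ternary not in ("early", "delayed", "plastic"):
                raise TraitValidationError(
                    f"{self.species}: learning_ternary {self.learning_ternary!r}"
                )
            binary_from_ternary = (
                "plastic" if self.learning_ternary == "plastic" else "stable"
            )
            if binary_from_ternary != self.learning_binary:
                raise TraitValidationError(
                    f"{self.species}: ternary {self.learning_ternary!r} "
                    f"inconsistent with binary {self.learning_binary!r}"
                )
        if self.learning_years is not None:
            if not (0.0 <= self.learning_years <= 2.0):
                raise TraitValidationError(
                    f"{self.species}: learning_years outside [0, 2]"
                )
            if self.learning_ternary == "plastic" and self.learning_years != PLASTIC_YEARS:
                raise TraitValidationError(
                    f"{self.species}: plastic species must have years = 2"
                )
        for trait in RAW_TRAITS:
            for v in getattr(self, trait):
                if not (v > 0) or not math.isfinite(v):
                    raise TraitValidationError(
                        f"{self.species}: {trait} value {v!r} must be > 0"
                    )
        for frac_name in ("polygynous_male_fraction", "epp_fraction"):
            frac = getattr(self, frac_name)
            if frac is not None and not (0.0 <= frac <= 1.0):
                raise TraitValidationError(
                    f"{self.species}: {frac_name} outside [0, 1]"
                )


@dataclass
class AnalysisDataset:
    """Tree-aligned analysis table (one aggregation mode, natural-log traits)."""

    table: pd.DataFrame  # index = species; ln trait columns + codings
    tree: Phylogeny
    aggregation: str
    skipped_species: list[str] = field(default_factory=list)

    def trait_values(self, trait: str) -> dict[str, float]:
        """Species -> ln trait value, rows with missing data dropped."""
        col = self.table[trait]
        return {sp: float(v) for sp, v in col.items() if pd.notna(v)}

    def labels(self, column: str) -> dict[str, object]:
        col = self.table[column]
        return {sp: v for sp, v in col.items() if pd.notna(v) and v is not None}


# ----------------------------------------------------------------------
# coding rules
# ----------------------------------------------------------------------

def code_learning_window(
    modifies_during_first_season: bool,
    modifies_after_first_season: bool,
    stabilization_age: float | None = None,
    delayed_plumage: bool = False,
) -> tuple[str, str, float]:
    """Code one species' learning window from a stabilization observation.

    Returns (binary, ternary, years).  Species whose song still changes
    after the first breeding season are plastic with years = 2; species
    that modify during but not after it are delayed-stable with years =
    1.33; species that stop beforehand are early-stable with the
    reported stabilization age (default 1.0, the end of the pre-breeding
    period, when no age was reported).  Delayed-plumage species are
    coded binary-stable with years = 2.
    """
    if modifies_after_first_season and not modifies_during_first_season:
        raise TraitValidationError(
            "contradictory observation: modifies after but not during "
            "the first breeding season"
        )
    if delayed_plumage:
        if modifies_after_first_season:
            raise TraitValidationError(
                "delayed-plumage exception applies only to species that stop "
                "modifying before their second (mature-plumage) season"
            )
        return "stable", "delayed", PLASTIC_YEARS
    if modifies_after_first_season:
        return "plastic", "plastic", PLASTIC_YEARS
    if modifies_during_first_season:
        return "stable", "delayed", DELAYED_YEARS
    if stabilization_age is None:
        stabilization_age = 1.0  # end of the pre-breeding period, flagged upstream
    if not (0.0 <= stabilization_age <= 1.0):
        raise TraitValidationError(
            "early-stable stabilization age must lie in [0, 1] years"
        )
    return "stable", "early", float(stabilization_age)


def aggregate_trait(values: Sequence[float], mode: str = "median") -> float | None:
    """Aggregate per-study values; empty input yields a missing marker."""
    vals = [float(v) for v in values]
    if not vals:
        return None
    if mode == "median":
        return float(np.median(vals))
    if mode == "min":
        return float(min(vals))
    if mode == "max":
        return float(max(vals))
    raise ValueError(f"unknown aggregation mode {mode!r}")


def derive_song_metrics(duration_s: float, interval_s: float) -> tuple[float, float]:
    """Rate = 60/(duration+interval); continuity = duration/(duration+interval)."""
    if duration_s <= 0:
        raise TraitValidationError("duration must be > 0")
    if interval_s < 0:
        raise TraitValidationError("interval must be >= 0")
    total = duration_s + interval_s
    if total == 0:
        raise TraitValidationError("duration + interval must be > 0")
    return 60.0 / total, duration_s / total


def impute_syllable_repertoire(
    record: SpeciesRecord, mode: str = "median"
) -> SpeciesRecord:
    """Single-song species: syllable repertoire = syllables per song.

    Applies only when the aggregated song repertoire equals exactly 1,
    the syllable repertoire is missing, and syllables per song is
    available; otherwise the record is returned unchanged.  The
    imputation is flagged on the returned record.
    """
    if record.syllable_repertoire:
        return record
    song_rep = aggregate_trait(record.song_repertoire, mode)
    if song_rep != 1.0:
        return record
    if not record.syllables_per_song:
        return record
    return replace(
        record,
        syllable_repertoire=list(record.syllables_per_song),
        imputed_syllable_repertoire=True,
    )


def classify_mating(
    polygynous_male_fraction: float | None, epp_fraction: float | None
) -> tuple[str | None, str | None]:
    """Binary mating classes: polygyny at >= 5% of males, high EPP at >= 10%."""
    mating = epp = None
    if polygynous_male_fraction is not None:
        if not (0.0 <= polygynous_male_fraction <= 1.0):
            raise TraitValidationError("polygynous fraction outside [0, 1]")
        mating = (
            "polygynous"
            if polygynous_male_fraction >= POLYGYNY_THRESHOLD
            else "monogamous"
        )
    if epp_fraction is not None:
        if not (0.0 <= epp_fraction <= 1.0):
            raise TraitValidationError("EPP fraction outside [0, 1]")
        epp = "high" if epp_fraction >= EPP_THRESHOLD else "low"
    return mating, epp


def binarize_by_threshold(
    values: Mapping[str, float], threshold: float
) -> tuple[dict[str, str], bool]:
    """Split a continuous trait at a threshold: high iff value > threshold.

    The strictly-greater convention means an observed value used as the
    threshold never empties the low class.  Returns the labels and a
    degeneracy flag set when either class is empty.
    """
    labels = {
        sp: ("high" if v > threshold else "low") for sp, v in values.items()
    }
    kinds = set(labels.values())
    degenerate = kinds != {"low", "high"}
    return labels, degenerate


# ----------------------------------------------------------------------
# dataset assembly
# ----------------------------------------------------------------------

def build_analysis_dataset(
    records: Iterable[SpeciesRecord],
    tree: Phylogeny,
    aggregation: str = "median",
    melospiza_override: bool = False,
    improviser_species: str | None = None,
) -> AnalysisDataset:
    """Aggregate, transform, and align species records to a tree.

    All seven song traits are natural-log transformed after aggregation;
    rate and continuity are derived from the aggregated duration and
    interval before the transform.  Species absent from the tree are
    skipped (reported, not fatal).  With ``melospiza_override`` the
    designated improviser species (by default the one named
    ``improviser_species``) is reclassified as song-stable — the
    sensitivity variant for species known only as open-ended
    improvisers, whose lifelong improvisation may not be lifelong
    learning.
    """
    records = [impute_syllable_repertoire(r, aggregation) for r in records]
    for r in records:
        r.validate()
    tip_set = set(tree.tip_labels)
    rows = []
    skipped = []
    for r in records:
        if r.species not in tip_set:
            skipped.append(r.species)
            continue
        row: dict[str, object] = {
            "species": r.species,
            "family": r.family,
            "learning_binary": r.learning_binary,
            "learning_ternary": r.learning_ternary,
            "learning_years": r.learning_years,
        }
        if melospiza_override and (
            improviser_species is None or r.species == improviser_species
        ):
            if improviser_species is None:
                raise ValueError(
                    "melospiza_override requires improviser_species"
                )
        if melospiza_override and r.species == improviser_species:
            row["learning_binary"] = "stable"
            row["learning_ternary"] = None
            row["learning_years"] = None
        agg = {t: aggregate_trait(getattr(r, t), aggregation) for t in RAW_TRAITS}
        rate = continuity = None
        if agg["duration_s"] is not None and agg["interval_s"] is not None:
            rate, continuity = derive_song_metrics(
                agg["duration_s"], agg["interval_s"]
            )
        full = dict(agg)
        full["rate_per_min"] = rate
        full["continuity"] = continuity
        for t in SONG_TRAITS:
            row[t] = math.log(full[t]) if full[t] is not None else np.nan
        mating, epp = classify_mating(
            r.polygynous_male_fraction, r.epp_fraction
        )
        row["mating_system"] = mating
        row["epp_class"] = epp
        rows.append(row)
    if not rows:
        raise TraitValidationError("no species shared between records and tree")
    table = pd.DataFrame(rows).set_index("species")
    keep = set(table.index)
    work_tree = prune_to_taxa(tree, keep) if keep != tip_set else tree
    return AnalysisDataset(
        table=table,
        tree=work_tree,
        aggregation=aggregation,
        skipped_species=skipped,
    )


# ----------------------------------------------------------------------
# CSV I/O
# ----------------------------------------------------------------------
# One row per species.  Multi-study trait values are ';'-joined in a
# single cell; empty cells are missing.  A column mapping can adapt
# externally deposited layouts to these names.

_LIST_SEP = ";"


def records_to_csv(records: Iterable[SpeciesRecord], path: str) -> None:
    rows = []
    for r in records:
        row = {
            "species": r.species,
            "family": r.family,
            "learning_binary": r.learning_binary,
            "learning_ternary": r.learning_ternary or "",
            "learning_years": "" if r.learning_years is None else r.learning_years,
            "polygynous_male_fraction": (
                "" if r.polygynous_male_fraction is None else r.polygynous_male_fraction
            ),
            "epp_fraction": "" if r.epp_fraction is None else r.epp_fraction,
        }
        for t in RAW_TRAITS:
            row[t] = _LIST_SEP.join(repr(v) for v in getattr(r, t))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def records_from_csv(
    path: str, column_map: Mapping[str, str] | None = None
) -> list[SpeciesRecord]:
    """Load species records; ``column_map`` renames external columns
    (e.g. a deposited dataset's headers) onto the canonical ones."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if column_map:
        df = df.rename(columns=dict(column_map))
    records = []
    for _, row in df.iterrows():
        kwargs: dict[str, object] = {
            "species": row["species"],
            "family": row.get("family", ""),
            "learning_binary": row["learning_binary"],
            "learning_ternary": row.get("learning_ternary") or None,
            "learning_years": (
                float(row["learning_years"]) if row.get("learning_years") else None
            ),
            "polygynous_male_fraction": (
                float(row["polygynous_male_fraction"])
                if row.get("polygynous_male_fraction")
                else None
            ),
            "epp_fraction": (
                float(row["epp_fraction"]) if row.get("epp_fraction") else None
            ),
        }
        for t in RAW_TRAITS:
            cell = row.get(t, "")
            kwargs[t] = [float(v) for v in cell.split(_LIST_SEP)] if cell else []
        rec = SpeciesRecord(**kwargs)
        rec.validate()
        records.append(rec)
    return records
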
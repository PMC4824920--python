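"""Occurrence (prevalence) statistics on the Wolbachia infection-status table.

The packaged fixture gives one row per filarial species with its Onchocercidae
clade (ONC1-ONC5), infection status, whether the species was newly screened,
whether a new Wolbachia strain was found in it, whether it belongs to the
45-species study sample, the evidence source, and the Wolbachia supergroup
when known.  All printed percentages are species-level, so specimen-level
duplicates are collapsed before counting.
"""
from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from typing import Optional, Sequence

import pandas as pd

from .errors import ValidationError

__all__ = ["OccurrenceResult", "make_infection_fixture", "compute_occurrence"]

_BOOL_COLUMNS = ("newly_examined", "new_strain", "in_study")


@dataclass(frozen=True)
class OccurrenceResult:
    """Infection occurrence within a described subset of species."""

    numerator: int
    denominator: int
    percentage: float  # 100 * numerator / denominator, half-up to 1 decimal
    subset: str

    @property
    def percentage_integer(self) -> int:
        """The percentage rounded half-up to the nearest integer."""
        return int(
            (Decimal(100 * self.numerator) / Decimal(self.denominator)).quantize(
                Decimal("1"), rounding=ROUND_HALF_UP
            )
        )


def make_infection_fixture() -> pd.DataFrame:
    """Load the packaged per-species Wolbachia infection-status table.

    The table is a synthetic transcription: rows whose ``citation`` column
    names a table or figure carry statuses stated in the source text; rows
    tagged ``reconstructed`` fill out the prior-report roster (whose full
    species list lives in a supplement outside the text) so that the
    published aggregate counts hold exactly - 45 study species of which 26
    are infected, 16 newly screened species with 7 new strains and 9
    negatives, and 85 species overall of which 45 are infected.
    """
    with resources.files("cophylo.data").joinpath("infection_status_synthetic.csv").open() as fh:
        df = pd.read_csv(fh, keep_default_na=False)
    for col in _BOOL_COLUMNS:
        df[col] = df[col].map({"True": True, "False": False, True: True, False: False})
    return df


def compute_occurrence(
    table: pd.DataFrame,
    clades: Optional[Sequence[str]] = None,
    in_study: Optional[bool] = None,
    newly_examined: Optional[bool] = None,
    source: Optional[str] = None,
    subset_name: Optional[str] = None,
) -> OccurrenceResult:
    """Fraction of distinct species with a positive status in a subset.

    Filters combine conjunctively; species are deduplicated (a species listed
    for several specimens counts once, and conflicting duplicate statuses are
    an error).  Raises when the subset is empty.
    """
    df = table
    desc = []
    if clades is not None:
        df = df[df["clade"].isin(list(clades))]
        desc.append(f"clade in {{{', '.join(clades)}}}")
    if in_study is not None:
        df = df[df["in_study"] == in_study]
        desc.append("study sample" if in_study else "prior reports only")
    if newly_examined is not None:
        df = df[df["newly_examined"] == newly_examined]
        desc.append("newly examined" if newly_examined else "previously examined")
    if source is not None:
        df = df[df["source"] == source]
        desc.append(f"source={source}")
    if df.empty:
        raise ValidationError("no species left after filtering; check the subset")
    bad = set(df["status"]) - {"positive", "negative"}
    if bad:
        raise ValidationError(f"status column must be positive/negative, found {bad}")
    per_species = df.groupby("species")["status"].agg(set)
    conflicts = per_species[per_species.map(len) > 1]
    if not conflicts.empty:
        raise ValidationError(
            f"conflicting statuses for species: {', '.join(conflicts.index)}"
        )
    statuses = per_species.map(lambda s: next(iter(s)))
    numerator = int((statuses == "positive").sum())
    denominator = int(len(statuses))
    pct = float(
        (Decimal(100 * numerator) / Decimal(denominator)).quantize(
            Decimal("0.1"), rounding=ROUND_HALF_UP
        )
    )
    return OccurrenceResult(
        numerator=numerator,
        denominator=denominator,
        percentage=pct,
        subset=subset_name or ("; ".join(desc) if desc else "all species"),
    )
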
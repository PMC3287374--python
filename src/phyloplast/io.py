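"""Tabular dataset I/O: one TSV row per case x treatment."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd

from .traits import StudyCase, TraitError, TreatmentSummary, volume_to_mass

__all__ = ["CASE_COLUMNS", "read_cases", "write_cases", "cases_to_frame"]

CASE_COLUMNS = [
    "case_id",
    "species",
    "population",
    "risk_group",
    "venue",
    "treatment",
    "period_mean",
    "period_sd",
    "period_n",
    "mass_mean",
    "mass_sd",
    "mass_n",
    "mass_is_volume",
]

TREATMENTS = ("constant", "drying")


def _summary_from_row(row: pd.Series) -> TreatmentSummary:
    mass_mean = float(row["mass_mean"])
    mass_sd = float(row["mass_sd"])
    if bool(row.get("mass_is_volume", False)):
        # density 1 g/mL: the map is the identity but keeps units honest
        mass_mean = volume_to_mass(mass_mean)
        mass_sd = mass_sd * 1.0
    return TreatmentSummary(
        period_mean=float(row["period_mean"]),
        period_sd=float(row["period_sd"]),
        period_n=int(row["period_n"]),
        mass_mean=mass_mean,
        mass_sd=mass_sd,
        mass_n=int(row["mass_n"]),
    )


def read_cases(path: Union[str, Path]) -> list[StudyCase]:
    """Read a case table (TSV) into StudyCase records.

    Rows sharing a case_id describe the same case under different
    treatments; `treatment` must be 'constant' or 'drying'.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in CASE_COLUMNS if c not in df.columns and c != "population"]
    if missing:
        raise TraitError(f"case table missing columns: {missing}")
    bad = sorted(set(df["treatment"]) - set(TREATMENTS))
    if bad:
        raise TraitError(f"unknown treatment values: {bad}")
    cases: list[StudyCase] = []
    for case_id, grp in df.groupby("case_id", sort=False):
        if grp.duplicated("treatment").any():
            raise TraitError(f"case {case_id!r} has duplicate treatment rows")
        meta = grp.iloc[0]
        summaries: dict[str, Optional[TreatmentSummary]] = {t: None for t in TREATMENTS}
        for _, row in grp.iterrows():
            summaries[row["treatment"]] = _summary_from_row(row)
        population = meta.get("population")
        if pd.isna(population):
            population = None
        cases.append(
            StudyCase(
                case_id=str(case_id),
                species=str(meta["species"]),
                risk_group=str(meta["risk_group"]),
                venue=str(meta["venue"]),
                constant=summaries["constant"],
                drying=summaries["drying"],
                population=population,
            )
        )
    return cases


def cases_to_frame(cases: Iterable[StudyCase]) -> pd.DataFrame:
    rows = []
    for case in cases:
        for treatment, ts in (("constant", case.constant), ("drying", case.drying)):
            if ts is None:
                continue
            rows.append(
                {
                    "case_id": case.case_id,
                    "species": case.species,
                    "population": case.population or "",
                    "risk_group": case.risk_group,
                    "venue": case.venue,
                    "treatment": treatment,
                    "period_mean": ts.period_mean,
                    "period_sd": ts.period_sd,
                    "period_n": ts.period_n,
                    "mass_mean": ts.mass_mean,
                    "mass_sd": ts.mass_sd,
                    "mass_n": ts.mass_n,
                    "mass_is_volume": False,
                }
            )
    return pd.DataFrame(rows, columns=CASE_COLUMNS)


def write_cases(cases: Iterable[StudyCase], path: Union[str, Path]) -> None:
    cases_to_frame(cases).to_csv(path, sep="\t", index=False)
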
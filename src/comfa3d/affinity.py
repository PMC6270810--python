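"""Binding-affinity tables and external-validation statistics.

This module is numbers-only: it carries Ki/pKi records for the CB1 and CB2
aminoalkylindole assay series (packaged as CSV fixtures), converts between
Ki and pKi, and computes the external-validation statistics used to judge a
3D-QSAR model on its held-out test set:

    PRESS   = sum over test molecules of (actual - predicted)^2
    SD      = sum over test molecules of (actual - mean_train_activity)^2
    r2_pred = (SD - PRESS) / SD

Higher r2_pred means the model predicts held-out activities better than the
naive "predict the training mean" baseline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal

import pandas as pd

__all__ = [
    "AffinityRecord",
    "AffinityTable",
    "PredictiveStats",
    "ki_to_pki",
    "load_fixture",
    "load_csv",
    "residuals",
    "predictive_stats",
    "RECEPTORS",
]

RECEPTORS = ("CB1", "CB2")

#: expected (train, test) record counts for the packaged assay tables
FIXTURE_SPLIT_COUNTS = {"CB1": (36, 13), "CB2": (60, 20)}


class AffinityError(ValueError):
    """Raised for invalid affinity values or malformed tables."""


def ki_to_pki(ki: float, unit: Literal["nM", "M"] = "nM") -> float:
    """Convert an inhibition constant Ki to pKi = -log10(Ki in molar).

    Parameters
    ----------
    ki : positive inhibition constant.
    unit : ``"nM"`` (default) or ``"M"``.
    """
    if not ki > 0:
        raise AffinityError(f"Ki must be positive, got {ki!r}")
    if unit == "nM":
        ki = ki * 1e-9
    elif unit != "M":
        raise AffinityError(f"unknown Ki unit {unit!r}")
    return -math.log10(ki)


@dataclass(frozen=True)
class AffinityRecord:
    """One molecule's affinity for one receptor, as printed in the source table.

    ``pki``/``predicted_pki``/``residual`` are stored exactly as printed
    (2-3 decimals); statistics over a table are therefore computed on the
    printed values and reproduce the source at printed precision.
    """

    molecule_id: int
    receptor: str
    ki_nanomolar: float
    pki: float
    predicted_pki: float | None = None
    residual: float | None = None
    split: Literal["train", "test"] = "train"
    #: decimals the Ki value was printed with (drives the consistency interval)
    ki_decimals: int = 1

    def __post_init__(self) -> None:
        if self.ki_nanomolar <= 0:
            raise AffinityError(
                f"molecule {self.molecule_id}: Ki must be positive, "
                f"got {self.ki_nanomolar}"
            )
        if self.split not in ("train", "test"):
            raise AffinityError(f"bad split {self.split!r}")

    def pki_consistent(self) -> bool:
        """Is the printed pKi consistent with the printed Ki?

        Both columns are rounded independently in the source, so the check
        is an interval one: the printed pKi (±0.0005 for its own rounding)
        must overlap [-log10((Ki+h) nM), -log10((Ki-h) nM)] where h is the
        half-ulp of the printed Ki.
        """
        half_ulp = 0.5 * 10.0 ** (-self.ki_decimals)
        lo = ki_to_pki(self.ki_nanomolar + half_ulp)
        hi = ki_to_pki(max(self.ki_nanomolar - half_ulp, 1e-12))
        return lo - 0.0005 <= self.pki <= hi + 0.0005

    def residual_consistent(self, tol: float = 0.00505) -> bool:
        """Does printed residual equal printed (actual - predicted) to rounding?"""
        if self.predicted_pki is None or self.residual is None:
            return True
        return abs((self.pki - self.predicted_pki) - self.residual) <= tol


@dataclass
class AffinityTable:
    """An ordered affinity table for a single receptor."""

    receptor: str
    records: list[AffinityRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.molecule_id for r in self.records]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise AffinityError(
                f"duplicate molecule ids in {self.receptor} table: {dupes}"
            )
        for r in self.records:
            if r.receptor != self.receptor:
                raise AffinityError(
                    f"record for {r.receptor} in {self.receptor} table"
                )

    def subset(self, which: Literal["train", "test", "all"]) -> list[AffinityRecord]:
        if which == "all":
            return list(self.records)
        if which not in ("train", "test"):
            raise AffinityError(f"unknown subset {which!r}")
        return [r for r in self.records if r.split == which]

    @property
    def n_train(self) -> int:
        return len(self.subset("train"))

    @property
    def n_test(self) -> int:
        return len(self.subset("test"))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "receptor": [r.receptor for r in self.records],
                "molecule_id": [r.molecule_id for r in self.records],
                "ki_nM": [r.ki_nanomolar for r in self.records],
                "pki": [r.pki for r in self.records],
                "predicted_pki": [r.predicted_pki for r in self.records],
                "residual": [r.residual for r in self.records],
                "split": [r.split for r in self.records],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class PredictiveStats:
    """External-validation sums over a test set (see module docstring)."""

    press: float
    sd: float
    r2_pred: float
    train_mean: float
    n_test: int


def _count_decimals(text: str) -> int:
    text = text.strip()
    return len(text.split(".", 1)[1]) if "." in text else 0


def _table_from_frame(df: pd.DataFrame, receptor: str) -> AffinityTable:
    records = []
    for row in df.itertuples(index=False):
        pred = None if pd.isna(row.predicted_pki) else float(row.predicted_pki)
        resid = None if pd.isna(row.residual) else _normalize_minus(row.residual)
        records.append(
            AffinityRecord(
                molecule_id=int(row.molecule_id),
                receptor=str(row.receptor),
                ki_nanomolar=float(row.ki_nM),
                pki=float(row.pki),
                predicted_pki=pred,
                residual=resid,
                split=str(row.split),
                ki_decimals=max(_count_decimals(str(row.ki_nM)), 1),
            )
        )
    return AffinityTable(receptor=receptor, records=records)


def _normalize_minus(value) -> float:
    # printed tables mix ASCII '-' with U+2212/U+2012 minus variants
    if isinstance(value, str):
        for ch in ("−", "‒", "–"):
            value = value.replace(ch, "-")
    return float(value)


def load_csv(path: str | Path, receptor: str | None = None) -> AffinityTable:
    """Load an affinity table from the CSV schema used by the fixtures.

    Columns: receptor, molecule_id, ki_nM, pki, predicted_pki, residual, split.
    """
    df = pd.read_csv(path, dtype={"ki_nM": str})
    required = {"receptor", "molecule_id", "ki_nM", "pki",
                "predicted_pki", "residual", "split"}
    missing = required - set(df.columns)
    if missing:
        raise AffinityError(f"{path}: missing columns {sorted(missing)}")
    df["ki_nM"] = df["ki_nM"].astype(str)
    decs = df["ki_nM"].map(_count_decimals)
    df = df.assign(_dec=decs)
    if receptor is None:
        receptors = df["receptor"].unique()
        if len(receptors) != 1:
            raise AffinityError(f"{path}: expected a single receptor, got {receptors}")
        receptor = receptors[0]
    table = _table_from_frame(df, receptor)
    # attach printed Ki precision per record
    table.records = [
        AffinityRecord(
            molecule_id=r.molecule_id, receptor=r.receptor,
            ki_nanomolar=r.ki_nanomolar, pki=r.pki,
            predicted_pki=r.predicted_pki, residual=r.residual, split=r.split,
            ki_decimals=max(int(d), 1),
        )
        for r, d in zip(table.records, decs)
    ]
    return table


def load_fixture(receptor: str) -> AffinityTable:
    """Load the packaged CB1 or CB2 affinity table.

    The fixtures transcribe the published assay table: CB1 carries 36
    training and 13 test molecules, CB2 60 and 20. Split counts are
    verified at load time.
    """
    if receptor not in RECEPTORS:
        raise AffinityError(f"unknown receptor {receptor!r}; expected one of {RECEPTORS}")
    name = f"{receptor.lower()}_affinity.csv"
    ref = resources.files("comfa3d.data").joinpath(name)
    with resources.as_file(ref) as path:
        if not path.exists():
            raise AffinityError(f"packaged fixture {name} is missing")
        table = load_csv(path, receptor=receptor)
    n_train, n_test = FIXTURE_SPLIT_COUNTS[receptor]
    if (table.n_train, table.n_test) != (n_train, n_test):
        raise AffinityError(
            f"corrupt fixture {name}: expected {n_train} train/{n_test} test, "
            f"got {table.n_train}/{table.n_test}"
        )
    return table


def residuals(
    table: AffinityTable, subset: Literal["train", "test", "all"] = "all"
) -> list[tuple[int, float]]:
    """(molecule_id, actual - predicted) over a subset, order preserved."""
    out = []
    for r in table.subset(subset):
        if r.predicted_pki is None:
            raise AffinityError(
                f"molecule {r.molecule_id} ({table.receptor}) has no prediction"
            )
        out.append((r.molecule_id, r.pki - r.predicted_pki))
    return out


def predictive_stats(table: AffinityTable) -> PredictiveStats:
    """PRESS, SD and predictive r^2 for a table with test-set predictions.

    Raises if SD is zero (r2_pred undefined: the test activities all equal
    the training mean) rather than silently reporting 0.
    """
    train = table.subset("train")
    test = table.subset("test")
    if not train or not test:
        raise AffinityError("need at least one train and one test record")
    missing = [r.molecule_id for r in test if r.predicted_pki is None]
    if missing:
        raise AffinityError(f"test molecules without predictions: {missing}")
    press = sum((r.pki - r.predicted_pki) ** 2 for r in test)
    train_mean = sum(r.pki for r in train) / len(train)
    sd = sum((r.pki - train_mean) ** 2 for r in test)
    if sd == 0:
        raise AffinityError(
            "SD is zero (all test activities equal the training mean); "
            "r2_pred is undefined"
        )
    return PredictiveStats(
        press=press,
        sd=sd,
        r2_pred=(sd - press) / sd,
        train_mean=train_mean,
        n_test=len(test),
    )


def table_from_predictions(
    receptor: str,
    molecule_ids: Iterable[int],
    ki_nM: Iterable[float],
    pki: Iterable[float],
    predicted: Iterable[float],
    split: Iterable[str],
) -> AffinityTable:
    """Assemble an AffinityTable from parallel sequences (pipeline output)."""
    records = [
        AffinityRecord(
            molecule_id=int(m), receptor=receptor, ki_nanomolar=float(k),
            pki=float(p), predicted_pki=float(pr),
            residual=float(p) - float(pr), split=s,
        )
        for m, k, p, pr, s in zip(molecule_ids, ki_nM, pki, predicted, split)
    ]
    return AffinityTable(receptor=receptor, records=records)
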
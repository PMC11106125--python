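"""Wide-format twin-pair tables and fitted-model reports.

A twin dataset is one row per pair: ``pair_id``, ``zygosity`` (MZ/DZ), then
``<var>_t1`` / ``<var>_t2`` columns for each phenotype plus per-twin ``age``
and ``sex`` covariates.  The wide layout matches the pairwise likelihood; no
long-format converter is provided.  Twin order within a pair is kept as given;
all model constraints downstream make results order-invariant.

Missing cells may be empty or ``NA``.  Rows with unknown zygosity are dropped
and counted, mirroring the exclusion of pairs with indeterminate zygosity.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .inference import FitResult

__all__ = [
    "SchemaError",
    "ParseError",
    "VariableSpec",
    "TwinDataset",
    "infer_variable_specs",
    "read_twin_table",
    "write_twin_table",
    "write_report",
    "read_report",
]

MZ, DZ = "MZ", "DZ"
_MISSING_TOKENS = {"", "NA", "NaN", "nan"}
COVARIATES = ("age", "sex")


class SchemaError(ValueError):
    """A mandatory column is missing or malformed."""


class ParseError(ValueError):
    """A cell could not be parsed; message names the row and column."""


@dataclass(frozen=True)
class VariableSpec:
    """Declares one phenotype: its measurement scale and model roles.

    A variable may be both dependent and moderator (the moderated-path models
    treat the moderator itself as a dependent variable).
    """

    name: str
    scale: str = "continuous"
    roles: frozenset = frozenset({"dependent"})
    n_categories: int | None = None

    def __post_init__(self):
        if self.scale not in ("continuous", "ordinal"):
            raise ValueError(f"unknown scale {self.scale!r}")
        object.__setattr__(self, "roles", frozenset(self.roles))
        bad = self.roles - {"dependent", "moderator", "covariate"}
        if bad:
            raise ValueError(f"unknown roles {sorted(bad)}")
        if self.scale == "ordinal":
            if self.n_categories is None or self.n_categories < 2:
                raise ValueError("ordinal variables need n_categories >= 2")

    @property
    def is_ordinal(self) -> bool:
        return self.scale == "ordinal"


class TwinDataset:
    """Validated wide-format twin-pair data plus variable declarations."""

    def __init__(self, table: pd.DataFrame, specs: Sequence[VariableSpec],
                 n_dropped: int = 0):
        self.specs = list(specs)
        self.n_dropped = int(n_dropped)
        self.table = table.reset_index(drop=True)
        self._validate()

    # -- construction / validation ----------------------------------------
    def _validate(self):
        t = self.table
        for col in ("pair_id", "zygosity"):
            if col not in t.columns:
                raise SchemaError(f"missing mandatory column {col!r}")
        bad_zyg = ~t["zygosity"].isin([MZ, DZ])
        if bad_zyg.any():
            raise SchemaError("zygosity must be 'MZ' or 'DZ' for every retained pair")
        for v in self.var_names + list(COVARIATES):
            for slot in ("t1", "t2"):
                col = f"{v}_{slot}"
                if col not in t.columns:
                    if v in COVARIATES:
                        t[col] = np.nan
                    else:
                        raise SchemaError(f"missing mandatory column {col!r}")
                t[col] = pd.to_numeric(t[col], errors="raise")
        for spec in self.specs:
            if spec.is_ordinal:
                vals = np.concatenate([t[f"{spec.name}_t1"], t[f"{spec.name}_t2"]])
                vals = vals[np.isfinite(vals)]
                if vals.size and (np.any(vals != np.round(vals)) or np.any(vals < 0)
                                  or np.any(vals >= spec.n_categories)):
                    raise SchemaError(
                        f"ordinal variable {spec.name!r} must use integer codes "
                        f"0..{spec.n_categories - 1}"
                    )
        ages = np.concatenate([t["age_t1"], t["age_t2"]])
        ages = ages[np.isfinite(ages)]
        if ages.size and np.any(ages < 0):
            raise SchemaError("ages must be nonnegative")

    # -- accessors ---------------------------------------------------------
    @property
    def var_names(self) -> list[str]:
        return [s.name for s in self.specs]

    @property
    def n_pairs(self) -> int:
        return len(self.table)

    def spec(self, name: str) -> VariableSpec:
        for s in self.specs:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def is_mz(self) -> np.ndarray:
        return (self.table["zygosity"] == MZ).to_numpy()

    def values(self, name: str) -> np.ndarray:
        """(n_pairs, 2) array of twin-1/twin-2 values (NaN = missing)."""
        return self.table[[f"{name}_t1", f"{name}_t2"]].to_numpy(dtype=float)

    def set_values(self, name: str, vals: np.ndarray) -> None:
        self.table[[f"{name}_t1", f"{name}_t2"]] = np.asarray(vals, dtype=float)

    def person_table(self, names: Iterable[str]) -> np.ndarray:
        """Stack twins into a (2*n_pairs, len(names)) per-person matrix."""
        cols = [self.values(n) for n in names]
        return np.column_stack([np.concatenate([c[:, 0], c[:, 1]]) for c in cols])

    def set_person_table(self, names: Iterable[str], mat: np.ndarray) -> None:
        n = self.n_pairs
        for j, name in enumerate(names):
            self.set_values(name, np.column_stack([mat[:n, j], mat[n:, j]]))

    def copy(self) -> "TwinDataset":
        return TwinDataset(self.table.copy(), list(self.specs), self.n_dropped)

    def swap_twins(self) -> "TwinDataset":
        """Exchange twin-1 and twin-2 columns (order-invariance checks)."""
        t = self.table.copy()
        for v in self.var_names + list(COVARIATES):
            t[[f"{v}_t1", f"{v}_t2"]] = t[[f"{v}_t2", f"{v}_t1"]].to_numpy()
        return TwinDataset(t, list(self.specs), self.n_dropped)

    def subset(self, mask: np.ndarray) -> "TwinDataset":
        return TwinDataset(self.table.loc[np.asarray(mask)].copy(), list(self.specs),
                           self.n_dropped)

    def __eq__(self, other) -> bool:
        if not isinstance(other, TwinDataset):
            return NotImplemented
        return (
            self.specs == other.specs
            and self.table.columns.tolist() == other.table.columns.tolist()
            and self.table.equals(other.table)
        )


def infer_variable_specs(table: pd.DataFrame, names: Sequence[str],
                         max_ordinal_levels: int = 10) -> list[VariableSpec]:
    """Infer per-variable scale from the data.

    A variable whose observed values are all integer codes in ``0..k-1`` with
    ``k <= max_ordinal_levels`` is declared ordinal with ``k`` categories
    (k at least 2); anything else is continuous.
    """
    specs = []
    for name in names:
        vals = pd.concat([table[f"{name}_t1"], table[f"{name}_t2"]]).to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        if (vals.size and np.all(vals == np.round(vals)) and vals.min() >= 0
                and vals.max() < max_ordinal_levels and len(np.unique(vals)) <= max_ordinal_levels):
            k = int(max(vals.max() + 1, 2))
            specs.append(VariableSpec(name, "ordinal", n_categories=k))
        else:
            specs.append(VariableSpec(name, "continuous"))
    return specs


def read_twin_table(path, specs: Sequence[VariableSpec] | None = None) -> TwinDataset:
    """Read a wide-format twin-pair CSV into a validated :class:`TwinDataset`.

    Pairs with blank/unknown zygosity are dropped and counted in
    ``dataset.n_dropped``.  When ``specs`` is omitted, variable scales are
    inferred with :func:`infer_variable_specs`.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in ("pair_id", "zygosity"):
        if col not in raw.columns:
            raise SchemaError(f"missing mandatory column {col!r} in {path}")
    var_names = sorted({
        c[:-3] for c in raw.columns if c.endswith(("_t1", "_t2"))
        and c[:-3] not in COVARIATES
    })
    for v in var_names:
        for slot in ("t1", "t2"):
            if f"{v}_{slot}" not in raw.columns:
                raise SchemaError(f"missing mandatory column '{v}_{slot}'")

    zyg = raw["zygosity"].str.strip().str.upper()
    keep = zyg.isin([MZ, DZ])
    n_dropped = int((~keep).sum())
    table = raw.loc[keep].copy()
    table["zygosity"] = zyg[keep]

    for col in table.columns:
        if col in ("pair_id", "zygosity"):
            continue
        parsed = []
        for idx, cell in table[col].items():
            cell = cell.strip()
            if cell in _MISSING_TOKENS:
                parsed.append(np.nan)
                continue
            try:
                parsed.append(float(cell))
            except ValueError:
                raise ParseError(
                    f"non-numeric value {cell!r} at row {idx}, column {col!r}"
                ) from None
        table[col] = parsed

    if specs is None:
        specs = infer_variable_specs(table, var_names)
    return TwinDataset(table, specs, n_dropped=n_dropped)


def write_twin_table(dataset: TwinDataset, path) -> None:
    """Write the pair table as RFC-4180 CSV (UTF-8, '.' decimal, NA missing)."""
    t = dataset.table.copy()
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(t.columns.tolist())
        for _, row in t.iterrows():
            out = []
            for col, v in row.items():
                if col in ("pair_id", "zygosity"):
                    out.append(str(v))
                elif v is None or (isinstance(v, float) and np.isnan(v)):
                    out.append("NA")
                else:
                    out.append(repr(float(v)))
            writer.writerow(out)


# -- fit reports -----------------------------------------------------------

def write_report(fit: FitResult, path) -> None:
    """Write a fit report as JSON plus a flat CSV parameter table.

    The JSON (at ``path``) round-trips bit-exactly through
    :func:`read_report`.  The CSV (same stem, ``.csv``) has one row per
    parameter with estimate and CI bounds.  Non-converged fits are flagged and
    their CIs omitted.
    """
    path = Path(path)
    d = fit.to_dict()
    if not fit.converged:
        d["ci95"] = {}
    try:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(d, fh, indent=1)
        csv_path = path.with_suffix(".csv")
        with open(csv_path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["parameter", "estimate", "ci_lo", "ci_hi", "free"])
            for name, est in fit.estimates.items():
                lo, hi = d["ci95"].get(name, ("", ""))
                writer.writerow([name, repr(float(est)), lo if lo == "" else repr(float(lo)),
                                 hi if hi == "" else repr(float(hi)),
                                 int(name not in fit.fixed)])
    except OSError as exc:
        raise OSError(f"cannot write report to {path}: {exc}") from exc


def read_report(path) -> FitResult:
    with open(path, encoding="utf-8") as fh:
        return FitResult.from_dict(json.load(fh))
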
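"""Clinical subgroup contrasts, the correlation screen and sensitivity reruns.

Canonical thresholds: symptom severity low/high at YBOCS <= 24 / > 24,
age of onset early/late at < 18 / >= 18 years, illness duration short/long
at <= 7 / > 7 years, medication as a single binary.  Patients missing the
stratification variable are excluded from that contrast only.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import EmptySubgroupError, ValidationError
from .table import SubjectTable

__all__ = [
    "ContrastSpec",
    "build_contrasts",
    "clinical_correlation_screen",
    "sensitivity_reruns",
    "YBOCS_THRESHOLD",
    "ONSET_THRESHOLD",
    "DURATION_THRESHOLD",
]

YBOCS_THRESHOLD = 24.0       # <= low severity, > high severity
ONSET_THRESHOLD = 18.0       # < early onset, >= late onset
DURATION_THRESHOLD = 7.0     # <= short, > long


def _is_hc(meta: pd.DataFrame) -> pd.Series:
    return meta["diagnosis"] == 0


def _is_case(meta: pd.DataFrame) -> pd.Series:
    return meta["diagnosis"] == 1


def _case_where(col: str, pred) -> Callable[[pd.DataFrame], pd.Series]:
    def f(meta: pd.DataFrame) -> pd.Series:
        v = meta[col]
        return _is_case(meta) & v.notna() & pred(v)
    return f


@dataclass
class ContrastSpec:
    """Two disjoint group filters over subject rows; group B is labeled 1."""

    name: str
    group_a: Callable[[pd.DataFrame], pd.Series]
    group_b: Callable[[pd.DataFrame], pd.Series]
    variable: str | None = None
    threshold: float | None = None
    population: str = "combined"  # pediatric / adult / combined

    def apply(self, table: SubjectTable) -> tuple[SubjectTable, np.ndarray]:
        """Filtered table plus binary labels (group B = 1).

        Raises :class:`EmptySubgroupError` if either side is empty.
        """
        meta = table.meta
        if self.population == "pediatric":
            meta_mask = meta["age"] < 18
        elif self.population == "adult":
            meta_mask = meta["age"] >= 18
        else:
            meta_mask = pd.Series(True, index=meta.index)
        a = (self.group_a(meta) & meta_mask).to_numpy()
        b = (self.group_b(meta) & meta_mask).to_numpy()
        if (a & b).any():
            raise ValidationError(f"contrast {self.name!r}: groups overlap")
        if a.sum() == 0 or b.sum() == 0:
            raise EmptySubgroupError(
                f"contrast {self.name!r}: empty side "
                f"(|A|={int(a.sum())}, |B|={int(b.sum())})"
            )
        keep = np.flatnonzero(a | b)
        y = b[keep].astype(int)
        return table.subset(keep), y

    def with_population(self, population: str) -> "ContrastSpec":
        return replace(self, name=f"{self.name}_{population}", population=population)


def build_contrasts(table: SubjectTable | None = None,
                    adult_only_onset: bool = False) -> list[ContrastSpec]:
    """The canonical contrast list.

    With ``adult_only_onset`` the age-of-onset contrasts are additionally
    emitted restricted to adults (late-onset patients do not occur in
    pediatric samples).
    """
    med = _case_where("medicated", lambda v: v == 1)
    unmed = _case_where("medicated", lambda v: v == 0)
    low = _case_where("ybocs", lambda v: v <= YBOCS_THRESHOLD)
    high = _case_where("ybocs", lambda v: v > YBOCS_THRESHOLD)
    early = _case_where("age_of_onset", lambda v: v < ONSET_THRESHOLD)
    late = _case_where("age_of_onset", lambda v: v >= ONSET_THRESHOLD)
    short = _case_where("illness_duration", lambda v: v <= DURATION_THRESHOLD)
    long_ = _case_where("illness_duration", lambda v: v > DURATION_THRESHOLD)

    cs = [
        ContrastSpec("hc_vs_medicated", _is_hc, med, "medicated"),
        ContrastSpec("hc_vs_unmedicated", _is_hc, unmed, "medicated"),
        ContrastSpec("medicated_vs_unmedicated", unmed, med, "medicated"),
        ContrastSpec("hc_vs_low_severity", _is_hc, low, "ybocs", YBOCS_THRESHOLD),
        ContrastSpec("hc_vs_high_severity", _is_hc, high, "ybocs", YBOCS_THRESHOLD),
        ContrastSpec("low_vs_high_severity", low, high, "ybocs", YBOCS_THRESHOLD),
        ContrastSpec("hc_vs_early_onset", _is_hc, early, "age_of_onset", ONSET_THRESHOLD),
        ContrastSpec("hc_vs_late_onset", _is_hc, late, "age_of_onset", ONSET_THRESHOLD),
        ContrastSpec("early_vs_late_onset", early, late, "age_of_onset", ONSET_THRESHOLD),
        ContrastSpec("hc_vs_short_duration", _is_hc, short, "illness_duration", DURATION_THRESHOLD),
        ContrastSpec("hc_vs_long_duration", _is_hc, long_, "illness_duration", DURATION_THRESHOLD),
        ContrastSpec("short_vs_long_duration", short, long_, "illness_duration", DURATION_THRESHOLD),
    ]
    if adult_only_onset:
        cs += [c.with_population("adult") for c in cs
               if c.variable == "age_of_onset"]
    return cs


_CLINICAL_TYPES = {
    "medicated": "dichotomous",
    "ybocs": "continuous",
    "age_of_onset": "continuous",
    "illness_duration": "continuous",
}


def clinical_correlation_screen(
    table: SubjectTable,
    alpha: float = 0.05,
    variables: list[str] | None = None,
) -> pd.DataFrame:
    """Pairwise correlations between clinical variables among patients.

    Dispatch: point-biserial for dichotomous-continuous pairs, phi for
    dichotomous pairs, Pearson for continuous pairs (all are Pearson on
    the coded values).  Pairwise-complete rows; Bonferroni over the number
    of evaluated pairs.  Constant variables skip their pairs with a
    recorded reason.
    """
    variables = variables or list(_CLINICAL_TYPES)
    cases = table.meta[_is_case(table.meta)]
    rows = []
    pairs = [
        (a, b) for i, a in enumerate(variables) for b in variables[i + 1:]
    ]
    for a, b in pairs:
        sub = cases[[a, b]].dropna()
        kind_a = _CLINICAL_TYPES.get(a, "continuous")
        kind_b = _CLINICAL_TYPES.get(b, "continuous")
        if {kind_a, kind_b} == {"dichotomous"}:
            kind = "phi"
        elif "dichotomous" in (kind_a, kind_b):
            kind = "point_biserial"
        else:
            kind = "pearson"
        if len(sub) < 3 or sub[a].nunique() < 2 or sub[b].nunique() < 2:
            rows.append({"var_a": a, "var_b": b, "type": kind, "n": len(sub),
                         "r": np.nan, "p": np.nan, "significant": False,
                         "skipped": True})
            continue
        r, p = sps.pearsonr(sub[a].astype(float), sub[b].astype(float))
        rows.append({"var_a": a, "var_b": b, "type": kind, "n": len(sub),
                     "r": float(r), "p": float(p), "significant": False,
                     "skipped": False})
    out = pd.DataFrame(rows)
    m = int((~out["skipped"]).sum())
    if m > 0:
        out.loc[~out["skipped"], "significant"] = (
            out.loc[~out["skipped"], "p"] <= alpha / m
        )
    return out


def intersect_contrasts(
    primary: ContrastSpec, split_var: str, threshold: float
) -> list[ContrastSpec]:
    """Cross the primary contrast's case side(s) with a median-style split."""
    lo = lambda v: v <= threshold  # noqa: E731
    hi = lambda v: v > threshold   # noqa: E731
    out = []
    for side, pred in (("low", lo), ("high", hi)):
        def make(group, pred=pred):
            def f(meta: pd.DataFrame) -> pd.Series:
                base = group(meta)
                v = meta[split_var]
                extra = v.notna() & pred(v)
                # HC rows carry no clinical values; never restrict them
                return base & (extra | _is_hc(meta))
            return f
        out.append(ContrastSpec(
            name=f"{primary.name}__{split_var}_{side}",
            group_a=make(primary.group_a),
            group_b=make(primary.group_b),
            variable=split_var,
            threshold=threshold,
        ))
    return out


def sensitivity_reruns(
    table: SubjectTable,
    primary: ContrastSpec,
    split_var: str,
    threshold: float,
    run: Callable[[SubjectTable, np.ndarray, str], float],
    min_cell: int = 50,
) -> pd.DataFrame:
    """Re-run a contrast within each level of a correlated clinical variable.

    ``run(table, y, name)`` executes the classification and returns the
    pooled AUC.  Cells with fewer than ``min_cell`` subjects per class are
    skipped (recorded).  Returns a comparison table of AUCs and deltas vs
    the unsplit contrast.
    """
    cases = table.meta[_is_case(table.meta)]
    if cases[split_var].isna().all():
        raise ValidationError(
            f"split variable {split_var!r} is missing for all patients; "
            "disable the sensitivity rerun"
        )
    sub, y = primary.apply(table)
    rows = [{
        "contrast": primary.name, "split": "none",
        "n_a": int((y == 0).sum()), "n_b": int((y == 1).sum()),
        "auc": run(sub, y, primary.name), "skipped": False,
    }]
    base_auc = rows[0]["auc"]
    for c in intersect_contrasts(primary, split_var, threshold):
        try:
            sub_c, y_c = c.apply(table)
        except EmptySubgroupError:
            rows.append({"contrast": c.name, "split": split_var, "n_a": 0,
                         "n_b": 0, "auc": np.nan, "skipped": True})
            continue
        n_a, n_b = int((y_c == 0).sum()), int((y_c == 1).sum())
        if min(n_a, n_b) < min_cell:
            rows.append({"contrast": c.name, "split": split_var, "n_a": n_a,
                         "n_b": n_b, "auc": np.nan, "skipped": True})
            continue
        rows.append({"contrast": c.name, "split": split_var, "n_a": n_a,
                     "n_b": n_b, "auc": run(sub_c, y_c, c.name),
                     "skipped": False})
    out = pd.DataFrame(rows)
    out["delta_vs_unsplit"] = out["auc"] - base_auc
    return out
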
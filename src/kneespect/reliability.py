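"""Observer-agreement analysis: intraclass correlation and difference tables.

The agreement index is the two-way random-effects, absolute-agreement,
single-measure intraclass correlation, ICC(2,1), computed from the two-way
ANOVA mean squares of an ``n`` subjects x ``k`` raters matrix::

    ICC = (MS_rows - MS_err) / (MS_rows + (k-1) MS_err + (k/n)(MS_cols - MS_err))

where rows are subjects and columns raters (observers or repeat sessions).
An ICC of 1 indicates perfect reliability; following the conventional
interpretation bands, 0.81-1.00 is *very good* and 0.61-0.80 *good*
reliability.  Negative estimates are reported raw (not truncated at zero) so
the estimator's sampling properties remain visible.

:func:`reliability_report` reproduces the layout of a standard two-observer,
two-session reliability study: per-target intra-observer ICCs (session 1 vs
session 2, per observer), the inter-observer ICC (observer 1 vs observer 2,
by default on session-1 readings), and a pooled "Total" row.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, UndefinedICCError

__all__ = [
    "icc",
    "reliability_band",
    "ICCReport",
    "reliability_report",
    "difference_table",
]

RATER_COLUMNS = ("subject", "target", "observer", "session", "value")


def icc(ratings) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    Parameters
    ----------
    ratings
        ``n x k`` array-like, one row per subject, one column per rater;
        complete cases only (no missing cells).

    Raises
    ------
    InsufficientDataError
        If ``n < 2`` or ``k < 2`` or any cell is missing.
    UndefinedICCError
        If the total variance is zero (all ratings identical).
    """
    x = np.asarray(ratings, dtype=np.float64)
    if x.ndim != 2:
        raise InsufficientDataError(f"ratings must be a 2D matrix, got ndim={x.ndim}")
    n, k = x.shape
    if n < 2:
        raise InsufficientDataError(f"ICC requires at least 2 subjects, got {n}")
    if k < 2:
        raise InsufficientDataError(f"ICC requires at least 2 raters, got {k}")
    if not np.all(np.isfinite(x)):
        raise InsufficientDataError("ratings matrix contains missing/non-finite cells")

    grand = x.mean()
    if np.all(x == x[:, [0]]):
        # perfect agreement across raters: exactly 1 (unless degenerate),
        # bypassing mean-square cancellation noise
        if np.all(x == grand):
            raise UndefinedICCError(
                "zero total variance: all ratings are identical, ICC undefined"
            )
        return 1.0
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * float(np.sum((row_means - grand) ** 2))
    ss_cols = n * float(np.sum((col_means - grand) ** 2))
    ss_total = float(np.sum((x - grand) ** 2))
    ss_err = ss_total - ss_rows - ss_cols

    ms_rows = ss_rows / (n - 1)
    ms_cols = ss_cols / (k - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))

    if ss_total <= 1e-12 * max(1.0, grand * grand):
        raise UndefinedICCError(
            "zero total variance: all ratings are identical, ICC undefined"
        )
    denom = ms_rows + (k - 1) * ms_err + (k / n) * (ms_cols - ms_err)
    if denom == 0:
        raise UndefinedICCError("ICC denominator is zero; estimate undefined")
    value = (ms_rows - ms_err) / denom
    # denominator - numerator = k*(1-1/n)*MS_err + (k/n)*MS_cols >= 0, so the
    # estimate cannot exceed 1; clip the floating-point cancellation residue.
    return min(value, 1.0)


def reliability_band(value: float) -> str:
    """Interpretation band for an ICC: very good (0.81-1), good (0.61-0.80)."""
    if value > 1:
        raise UndefinedICCError(f"ICC cannot exceed 1, got {value}")
    if value >= 0.81:
        return "very good"
    if value >= 0.61:
        return "good"
    return "below good"


def _validate_dataset(data: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in RATER_COLUMNS if c not in data.columns]
    if missing:
        raise InsufficientDataError(f"rater dataset lacks column(s): {missing}")
    dup = data.duplicated(subset=["subject", "target", "observer", "session"])
    if dup.any():
        raise InsufficientDataError(
            f"{int(dup.sum())} duplicate (subject, target, observer, session) cell(s)"
        )
    return data


def _pivot(frame: pd.DataFrame, columns: str) -> pd.DataFrame:
    """Subjects x raters matrix, complete cases only."""
    wide = frame.pivot_table(index="subject", columns=columns, values="value", aggfunc="first")
    return wide.dropna(axis=0, how="any")


def _session_pairs(frame: pd.DataFrame, observers, pairing: str) -> pd.DataFrame:
    """Subjects x observers matrix for the inter-observer ICC."""
    if pairing == "session1":
        first = sorted(frame["session"].unique())[0]
        sub = frame[frame["session"] == first]
        return _pivot(sub, "observer")[list(observers)]
    if pairing == "mean":
        wide = frame.pivot_table(index="subject", columns="observer", values="value", aggfunc="mean")
        return wide.dropna(axis=0, how="any")[list(observers)]
    raise InsufficientDataError(
        f"unknown session pairing {pairing!r}; expected 'session1' or 'mean'"
    )


@dataclass
class ICCReport:
    """Per-target and pooled ICCs with interpretation bands."""

    table: pd.DataFrame
    session_pairing: str


def _safe_icc(matrix: pd.DataFrame, what: str) -> float:
    try:
        return icc(matrix.to_numpy())
    except (InsufficientDataError, UndefinedICCError) as exc:
        warnings.warn(f"{what}: {exc}; reported as NaN", stacklevel=3)
        return float("nan")


def reliability_report(
    data: pd.DataFrame, session_pairing: str = "session1"
) -> ICCReport:
    """Intra- and inter-observer ICCs per target plus a pooled Total row.

    ``data`` is the long-format rater dataset with columns
    ``subject, target, observer, session, value`` (two observers and two
    sessions in the canonical design; other balanced designs are accepted:
    intra-observer ICCs use all of an observer's sessions as raters, the
    inter-observer ICC all observers under the chosen session pairing).
    Targets with unbalanced or insufficient complete cases are excluded with
    an explicit warning rather than silently dropped.
    """
    data = _validate_dataset(pd.DataFrame(data))
    observers = sorted(data["observer"].unique())
    sessions = sorted(data["session"].unique())
    if len(observers) < 2:
        raise InsufficientDataError("inter-observer ICC requires >= 2 observers")
    if len(sessions) < 2:
        warnings.warn("single session: intra-observer ICCs unavailable", stacklevel=2)

    targets = list(dict.fromkeys(data["target"]))
    rows = []
    # Pooled matrices accumulate (subject, target) pairs as rows.
    pooled = data.assign(subject=data["subject"].astype(str) + "||" + data["target"].astype(str))
    for name, frame in [(t, data[data["target"] == t]) for t in targets] + [("Total", pooled)]:
        row: dict[str, object] = {"location": name, "n_subjects": frame["subject"].nunique()}
        for obs in observers:
            if len(sessions) >= 2:
                mat = _pivot(frame[frame["observer"] == obs], "session")
                value = (
                    _safe_icc(mat, f"intra-observer ICC ({name}, observer {obs})")
                    if len(mat) >= 2
                    else float("nan")
                )
                if len(mat) < 2:
                    warnings.warn(
                        f"target {name!r}, observer {obs}: fewer than 2 complete "
                        "subjects; intra-observer ICC excluded",
                        stacklevel=2,
                    )
            else:
                value = float("nan")
            row[f"intra_obs{obs}"] = value
        inter_mat = _session_pairs(frame, observers, session_pairing)
        if len(inter_mat) >= 2:
            row["inter"] = _safe_icc(inter_mat, f"inter-observer ICC ({name})")
        else:
            warnings.warn(
                f"target {name!r}: fewer than 2 complete subjects; "
                "inter-observer ICC excluded",
                stacklevel=2,
            )
            row["inter"] = float("nan")
        row["band"] = (
            reliability_band(row["inter"]) if np.isfinite(row["inter"]) else "undefined"
        )
        rows.append(row)
    return ICCReport(table=pd.DataFrame(rows), session_pairing=session_pairing)


def difference_table(data: pd.DataFrame, targets: list[str] | None = None) -> pd.DataFrame:
    """Median and range of absolute paired differences, inter- and intra-observer.

    Inter-observer differences pair the two observers' readings within each
    session; intra-observer differences pair each observer's two sessions.
    One row per (target, kind) with the raw ``median``/``min``/``max`` and a
    human-readable ``formatted`` column rounded to integer degrees, e.g.
    ``"1 (0-2)"``.
    """
    data = _validate_dataset(pd.DataFrame(data))
    if targets is None:
        targets = list(dict.fromkeys(data["target"]))
    rows = []
    for target in targets:
        frame = data[data["target"] == target]
        if frame.empty:
            raise InsufficientDataError(f"no records for target {target!r}")
        observers = sorted(frame["observer"].unique())
        sessions = sorted(frame["session"].unique())
        inter: list[np.ndarray] = []
        for s in sessions:
            wide = _pivot(frame[frame["session"] == s], "observer")
            for i, a in enumerate(observers):
                for b in observers[i + 1 :]:
                    if a in wide.columns and b in wide.columns:
                        inter.append(np.abs(wide[a].to_numpy() - wide[b].to_numpy()))
        intra: list[np.ndarray] = []
        for obs in observers:
            wide = _pivot(frame[frame["observer"] == obs], "session")
            for i, a in enumerate(sessions):
                for b in sessions[i + 1 :]:
                    if a in wide.columns and b in wide.columns:
                        intra.append(np.abs(wide[a].to_numpy() - wide[b].to_numpy()))
        for kind, diffs in (("inter-observer", inter), ("intra-observer", intra)):
            if kind == "intra-observer" and len(sessions) < 2:
                continue
            values = np.concatenate(diffs) if diffs else np.array([])
            if values.size == 0:
                raise InsufficientDataError(
                    f"no paired values for target {target!r} ({kind})"
                )
            med, lo, hi = float(np.median(values)), float(values.min()), float(values.max())
            rows.append(
                {
                    "target": target,
                    "kind": kind,
                    "n_pairs": int(values.size),
                    "median": med,
                    "min": lo,
                    "max": hi,
                    "formatted": f"{round(med):d} ({round(lo):d}–{round(hi):d})",
                }
            )
    return pd.DataFrame(rows)
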
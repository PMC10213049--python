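"""Covariate association tests and recovery metrics.

Association between strain sharing and perinatal covariates is tested per
covariate with no multiple-testing correction (deliberately matching the
study design this package emulates): Fisher's exact test for 2x2 tables,
Pearson chi-square (no continuity correction) for covariates with more
than two levels. The unit of analysis is the dyad (shared: yes/no).
Recovery metrics score calls against simulation ground truth with standard
confusion-matrix definitions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from straindyad.errors import InputError
from straindyad.simcohort import CohortTruth
from straindyad.transmission import METHODS, TransmissionCall


@dataclass
class ContingencyTable:
    """Covariate-level by outcome (shared / not shared) count table."""

    row_labels: list[str]
    col_labels: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise InputError("counts shape must match labels")
        if np.any(self.counts < 0):
            raise InputError("counts must be >= 0")


def _as_counts(table) -> np.ndarray:
    if isinstance(table, ContingencyTable):
        return table.counts
    return np.asarray(table, dtype=np.int64)


def chi_square_test(table) -> tuple[float, int, float]:
    """Pearson chi-square with no continuity correction.

    Returns (statistic, dof, p). Refuses tables with a zero expected cell
    (i.e. a zero margin) and directs the caller to Fisher's exact test.
    """
    counts = _as_counts(table)
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise InputError("chi-square needs at least a 2x2 table")
    n = counts.sum()
    expected = np.outer(counts.sum(axis=1), counts.sum(axis=0)) / n if n else np.zeros_like(counts, dtype=float)
    if n == 0 or np.any(expected == 0):
        raise InputError("zero expected cell; use fisher_exact instead")
    stat, p, dof, _ = stats.chi2_contingency(counts, correction=False)
    return float(stat), int(dof), float(p)


def fisher_exact(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table (sum of hypergeometric
    probabilities no larger than the observed table's). Larger tables are
    refused in favour of the chi-square test."""
    counts = _as_counts(table)
    if counts.shape != (2, 2):
        raise InputError("fisher_exact handles 2x2 tables only; use chi_square_test")
    _, p = stats.fisher_exact(counts, alternative="two-sided")
    return float(p)


def contingency_from_labels(
    shared: Mapping[str, bool], covariate: Mapping[str, str]
) -> ContingencyTable:
    """Dyad-level contingency table: covariate levels x (shared, not_shared)."""
    levels = sorted({covariate[d] for d in shared})
    counts = np.zeros((len(levels), 2), dtype=np.int64)
    idx = {lv: i for i, lv in enumerate(levels)}
    for dyad, flag in shared.items():
        counts[idx[covariate[dyad]], 0 if flag else 1] += 1
    return ContingencyTable(levels, ["shared", "not_shared"], counts)


def covariate_screen(
    shared: Mapping[str, bool],
    covariates: pd.DataFrame,
    alpha: float = 0.05,
    correction: str | None = None,
) -> pd.DataFrame:
    """Per-covariate association screen against dyad-level sharing.

    ``covariates`` is indexed by dyad id with one categorical column per
    covariate. 2x2 tables use Fisher's exact test, larger ones Pearson
    chi-square without correction; no multiple-testing correction is
    applied by default (set ``correction='bh'`` for Benjamini-Hochberg).
    Constant covariates are skipped with a note. ``direction`` is the
    level with the highest sharing rate.
    """
    missing = [d for d in shared if d not in covariates.index]
    if missing:
        raise InputError(f"covariates missing for dyads {missing[:5]}")
    rows = []
    for cov in covariates.columns:
        mapping = {d: str(covariates.at[d, cov]) for d in shared}
        levels = sorted(set(mapping.values()))
        if len(levels) < 2:
            rows.append({"covariate": cov, "test": "skipped", "p": np.nan,
                         "direction": "", "significant": False,
                         "note": "constant covariate"})
            continue
        table = contingency_from_labels(shared, mapping)
        rates = {
            lv: (table.counts[i, 0] / table.counts[i].sum()) if table.counts[i].sum() else 0.0
            for i, lv in enumerate(table.row_labels)
        }
        direction = max(sorted(rates), key=lambda lv: rates[lv])
        if len(levels) == 2:
            test, p = "fisher", fisher_exact(table)
        else:
            try:
                stat, dof, p = chi_square_test(table)
                test = "chi_square"
            except InputError:
                test, p = "skipped", np.nan
        rows.append({"covariate": cov, "test": test, "p": p,
                     "direction": direction, "significant": bool(p <= alpha) if np.isfinite(p) else False,
                     "note": "" if test != "skipped" else "degenerate table"})
    out = pd.DataFrame(rows)
    if correction == "bh":
        mask = np.isfinite(out["p"].to_numpy(dtype=float))
        p = out.loc[mask, "p"].to_numpy(dtype=float)
        order = np.argsort(p)
        m = len(p)
        adj = np.empty(m)
        running = 1.0
        for rank in range(m - 1, -1, -1):
            running = min(running, p[order[rank]] * m / (rank + 1))
            adj[order[rank]] = running
        out.loc[mask, "p_adjusted"] = adj
        out.loc[mask, "significant"] = adj <= alpha
    return out


def recovery_metrics(calls: Sequence[TransmissionCall], truth: CohortTruth) -> pd.DataFrame:
    """Confusion counts and sensitivity/specificity/precision per method
    and for the integrated (OR) call.

    The universe of units is every (dyad, species) carried by the cohort;
    a method's absent flag counts as a negative prediction (the method did
    not detect the event). Calls outside the truth universe raise an error.
    """
    universe = {
        (d.dyad_id, sp) for d in truth.dyads for sp in truth.config.species
    }
    positives = {(t.dyad_id, t.species) for t in truth.true_transmissions}
    unknown = [(c.dyad_id, c.species) for c in calls if (c.dyad_id, c.species) not in universe]
    if unknown:
        raise InputError(f"calls outside the truth universe: {unknown[:5]}")
    by_unit = {(c.dyad_id, c.species): c for c in calls}
    rows = []
    for method in METHODS + ("integrated",):
        tp = fp = fn = tn = 0
        for unit in sorted(universe):
            call = by_unit.get(unit)
            if call is None:
                pred = False
            elif method == "integrated":
                pred = call.transmitted
            else:
                pred = call.evidence.get(method) is True
            actual = unit in positives
            if pred and actual:
                tp += 1
            elif pred and not actual:
                fp += 1
            elif not pred and actual:
                fn += 1
            else:
                tn += 1
        rows.append({
            "method": method, "tp": tp, "fp": fp, "fn": fn, "tn": tn,
            "sensitivity": tp / (tp + fn) if tp + fn else np.nan,
            "specificity": tn / (tn + fp) if tn + fp else np.nan,
            "precision": tp / (tp + fp) if tp + fp else np.nan,
        })
    return pd.DataFrame(rows)
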
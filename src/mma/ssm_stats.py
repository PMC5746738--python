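"""Statistically significant metabolite (SSM) calling.

A metabolite is an SSM when its replicate peak areas differ significantly
between two timepoints under a two-sided Mann-Whitney U (rank-sum) test,
and its direction (accumulated / depleted) is read off the sign of the
median shift.  Because tissue extraction is not compartment-specific, an
SSM call on a measured base name is expanded to *all* compartmental
versions of that metabolite in the model.

Both the exact U distribution and the tie/continuity-corrected normal
approximation are available.  With very small replicate groups the exact
two-sided test has a coarse attainable p-value grid — at n = m = 3 its
minimum is 0.1, so no call can pass alpha = 0.05; the normal approximation
is the only route to sub-0.05 p-values at that depth.  The ``auto`` method
uses the exact distribution for groups of <= 8 without ties, otherwise the
normal approximation.

No multiple-testing correction is applied by default (raw p < alpha);
Benjamini-Hochberg is available behind ``correction="bh"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from mma.model_io import CompartmentMap, MetabolicModel

logger = logging.getLogger(__name__)

Direction = Literal["accumulated", "depleted", "none"]


@dataclass(frozen=True)
class MetabolomicsDataset:
    """Long-format replicate peak areas: one row per measurement."""

    table: pd.DataFrame  # columns: base_name, timepoint, replicate, peak_area

    REQUIRED = ("base_name", "timepoint", "replicate", "peak_area")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"dataset missing columns: {missing}")
        if (self.table["peak_area"] < 0).any():
            raise ValueError("peak areas must be non-negative")
        if self.table["timepoint"].nunique() < 2:
            raise ValueError("dataset must contain at least two timepoints")

    @classmethod
    def from_long(cls, path: str | Path, sep: str | None = None) -> "MetabolomicsDataset":
        """Read a long-format CSV/TSV (delimiter sniffed from the suffix)."""
        path = Path(path)
        if sep is None:
            sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
        return cls(pd.read_csv(path, sep=sep))

    @classmethod
    def from_wide(cls, path: str | Path, sep: str | None = None) -> "MetabolomicsDataset":
        """Read a wide CSV: first column metabolite, remaining columns named
        ``<timepoint>_<replicate>`` (e.g. ``t0_1``)."""
        path = Path(path)
        if sep is None:
            sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
        wide = pd.read_csv(path, sep=sep)
        name_col = wide.columns[0]
        rows = []
        for col in wide.columns[1:]:
            tp, _, rep = col.rpartition("_")
            if not tp:
                raise ValueError(
                    f"wide column {col!r} is not of the form <timepoint>_<replicate>"
                )
            for name, value in zip(wide[name_col], wide[col]):
                rows.append((name, tp, rep, value))
        return cls(
            pd.DataFrame(rows, columns=["base_name", "timepoint", "replicate", "peak_area"])
        )

    def timepoints(self) -> list[str]:
        return sorted(map(str, self.table["timepoint"].unique()))

    def groups(self, base_name: str, timepoint: str) -> np.ndarray:
        tbl = self.table
        mask = (tbl["base_name"] == base_name) & (tbl["timepoint"].astype(str) == str(timepoint))
        return tbl.loc[mask, "peak_area"].to_numpy(dtype=float)


@dataclass
class SSMTable:
    """Per-metabolite significance calls, optionally expanded to model nodes."""

    calls: pd.DataFrame  # columns: base_name, p_value, direction, is_ssm
    alpha: float
    ssm_nodes: frozenset[str] = frozenset()
    unmatched: frozenset[str] = frozenset()  # SSM base names with no model mapping

    def ssm_base_names(self) -> frozenset[str]:
        return frozenset(self.calls.loc[self.calls["is_ssm"], "base_name"])

    @property
    def n_ssm(self) -> int:
        return int(self.calls["is_ssm"].sum())

    def to_tsv(self, path: str | Path) -> None:
        self.calls.to_csv(path, sep="\t", index=False)

    def nodes_to_tsv(self, path: str | Path) -> None:
        pd.DataFrame({"node_id": sorted(self.ssm_nodes)}).to_csv(
            path, sep="\t", index=False
        )


def _rank_sum_p(
    x: np.ndarray, y: np.ndarray, method: Literal["exact", "normal_approx", "auto"]
) -> float:
    """Two-sided Mann-Whitney p-value under the requested convention."""
    if method == "auto":
        has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
        method = "exact" if (len(x) <= 8 and len(y) <= 8 and not has_ties) else "normal_approx"
    scipy_method = "exact" if method == "exact" else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=scipy_method)
    return float(min(res.pvalue, 1.0))


def call_ssms(
    data: MetabolomicsDataset,
    t0: str,
    t1: str,
    alpha: float = 0.05,
    method: Literal["exact", "normal_approx", "auto"] = "auto",
    correction: Literal["none", "bh"] = "none",
) -> SSMTable:
    """Call SSMs by comparing replicate peak areas between two timepoints.

    Per metabolite: a two-sided rank-sum p-value; direction from the sign
    of ``median(t1) - median(t0)``.  Metabolites measured at only one of
    the two timepoints get ``p = 1, direction = "none"``.  Equal medians
    force ``direction = "none"`` and ``is_ssm = False`` even when
    ``p < alpha`` (an SSM must be accumulated *or* depleted).
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    tps = {str(t) for t in data.table["timepoint"].unique()}
    for tp in (t0, t1):
        if str(tp) not in tps:
            raise ValueError(f"timepoint {tp!r} not present in dataset (have {sorted(tps)})")

    tbl = data.table
    tp = tbl["timepoint"].astype(str)
    by_name: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for name, sub in tbl.assign(_tp=tp).groupby("base_name", sort=False):
        values = sub["peak_area"].to_numpy(dtype=float)
        sub_tp = sub["_tp"].to_numpy()
        by_name[name] = (values[sub_tp == str(t0)], values[sub_tp == str(t1)])

    rows = []
    for base_name in pd.unique(tbl["base_name"]):
        g0, g1 = by_name[base_name]
        if len(g0) == 0 or len(g1) == 0:
            logger.warning(
                "metabolite %r measured at only one of %r/%r; skipped (p=1)",
                base_name, t0, t1,
            )
            rows.append((base_name, 1.0, "none"))
            continue
        p = _rank_sum_p(g0, g1, method)
        shift = float(np.median(g1) - np.median(g0))
        if shift > 0:
            direction: Direction = "accumulated"
        elif shift < 0:
            direction = "depleted"
        else:
            direction = "none"
        rows.append((base_name, p, direction))

    calls = pd.DataFrame(rows, columns=["base_name", "p_value", "direction"])
    p_eff = calls["p_value"].to_numpy(dtype=float)
    if correction == "bh":
        p_eff = _benjamini_hochberg(p_eff)
        calls["p_adjusted"] = p_eff
    is_ssm = (p_eff < alpha) & (calls["direction"] != "none")
    forced = (p_eff < alpha) & (calls["direction"] == "none")
    if forced.any():
        logger.info(
            "%d metabolites significant but with equal medians; not called SSM",
            int(forced.sum()),
        )
    calls["is_ssm"] = is_ssm
    return SSMTable(calls=calls, alpha=alpha)


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(n, dtype=float)
    running = 1.0
    for rank_idx in range(n - 1, -1, -1):
        i = order[rank_idx]
        running = min(running, p[i] * n / (rank_idx + 1))
        adj[i] = running
    return adj


def expand_to_model(
    ssm_table: SSMTable,
    compartment_map: CompartmentMap,
    model: MetabolicModel,
) -> SSMTable:
    """Expand SSM base-name calls to all mapped compartmental model nodes.

    Never removes calls: the per-base-name flags are preserved verbatim;
    SSM base names with no mapping are collected in ``unmatched``.
    """
    nodes: set[str] = set()
    unmatched: set[str] = set()
    known = set(model.metabolites_by_id)
    for base_name in ssm_table.ssm_base_names():
        mapped = compartment_map.get(base_name)
        if not mapped:
            unmatched.add(base_name)
            continue
        stray = mapped - known
        if stray:
            raise ValueError(
                f"compartment map for {base_name!r} references node_ids absent "
                f"from model: {sorted(stray)}"
            )
        nodes.update(mapped)
    if unmatched:
        logger.warning(
            "%d SSM base names had no model mapping: %s",
            len(unmatched), ", ".join(sorted(unmatched)),
        )
    return replace(
        ssm_table, ssm_nodes=frozenset(nodes), unmatched=frozenset(unmatched)
    )
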
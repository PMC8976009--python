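"""Scientist-volunteer agreement via confusion matrices.

Scientist and volunteer reports made on the same day, trail, plot, and
species are paired — the scientist record is the reference — and each of the
four phenophase assessments becomes one paired binary comparison. The four
confusion cells use the scientist(S)/community-volunteer(C), yes(Y)/no(N)
naming:

    sy_cy  true positives   (both record presence)
    sn_cn  true negatives   (both record absence)
    sn_cy  false positives  (volunteer presence, scientist absence)
    sy_cn  false negatives  (scientist presence, volunteer absence)

from which

    accuracy    = (sy_cy + sn_cn) / total
    sensitivity = sy_cy / (sy_cy + sy_cn)      TP / (TP + FN)
    specificity = sn_cn / (sn_cn + sn_cy)      TN / (TN + FP)

A metric whose denominator is zero is *undefined* and propagates as missing
(NaN), never as 0 or 1 — small strata must not fabricate perfect scores.
The terminology quantifies agreement only; it does not presume the
scientist is infallible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from snowbloom.species import PHENOPHASES

PHASE_COLUMNS = {"bud": "Bud", "flower": "Flower", "fruit": "Fruit", "disperse": "Disperse"}

PAIR_KEY = ["Date", "Transect", "Site_Code", "Species"]


@dataclass(frozen=True)
class ConfusionCounts:
    """The four cells of one 2x2 scientist-vs-volunteer confusion matrix."""

    sy_cy: int
    sn_cn: int
    sn_cy: int
    sy_cn: int

    @property
    def total(self) -> int:
        return self.sy_cy + self.sn_cn + self.sn_cy + self.sy_cn


def pair_reports(
    records: pd.DataFrame,
    collapse: str = "any",
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Pair volunteer reports with the same-key scientist reference.

    For every (date, transect, site, species) key holding at least one
    scientist and one volunteer record, each volunteer record is paired
    against the scientist reference and yields one row per phenophase.
    Multiple scientist records on one key are collapsed to a single
    reference: ``collapse="any"`` records a phenophase present if any
    scientist saw it (default); ``collapse="first"`` takes the first record.

    Returns
    -------
    pairs : DataFrame with columns Date, Transect, Site_Code, Species,
        phenophase, scientist, volunteer — one row per paired phenophase
        assessment.
    stats : pairing tallies (paired keys, unpaired scientist-only /
        volunteer-only keys, pairs emitted).
    """
    if collapse not in ("any", "first"):
        raise ValueError(f"collapse must be 'any' or 'first', got {collapse!r}")
    df = records
    stats = {"keys_paired": 0, "keys_scientist_only": 0, "keys_volunteer_only": 0,
             "assessments": 0}
    rows: list[dict] = []
    for key, g in df.groupby(PAIR_KEY, sort=True):
        sci = g[g["Scientist_or_volunteer"] == "Scientist"]
        vol = g[g["Scientist_or_volunteer"] == "Volunteer"]
        if len(sci) == 0 or len(vol) == 0:
            if len(sci):
                stats["keys_scientist_only"] += 1
            else:
                stats["keys_volunteer_only"] += 1
            continue
        stats["keys_paired"] += 1
        for phase, col in PHASE_COLUMNS.items():
            s_vals = sci[col].dropna().astype(int)
            if len(s_vals) == 0:
                continue
            ref = int(s_vals.max()) if collapse == "any" else int(s_vals.iloc[0])
            for v in vol[col].dropna().astype(int):
                rows.append(
                    {
                        "Date": key[0],
                        "Transect": key[1],
                        "Site_Code": key[2],
                        "Species": key[3],
                        "phenophase": phase,
                        "scientist": ref,
                        "volunteer": int(v),
                    }
                )
                stats["assessments"] += 1
    pairs = pd.DataFrame(
        rows,
        columns=["Date", "Transect", "Site_Code", "Species", "phenophase",
                 "scientist", "volunteer"],
    )
    return pairs, stats


_STRATA_COLS = {"phenophase": "phenophase", "species": "Species", "transect": "Transect"}


def tabulate(pairs: pd.DataFrame, stratify_by: list[str] | None = None) -> pd.DataFrame:
    """Confusion counts per stratum.

    ``stratify_by`` is a subset of {"phenophase", "species", "transect"};
    empty/None gives a single pooled row. Cells always sum to the stratum's
    pair count.
    """
    stratify_by = list(stratify_by or [])
    for s in stratify_by:
        if s not in _STRATA_COLS:
            raise ValueError(f"unknown stratum {s!r}; choose from {sorted(_STRATA_COLS)}")
    cols = [_STRATA_COLS[s] for s in stratify_by]

    def _cells(g: pd.DataFrame) -> pd.Series:
        s = g["scientist"].to_numpy()
        v = g["volunteer"].to_numpy()
        return pd.Series(
            {
                "sy_cy": int(((s == 1) & (v == 1)).sum()),
                "sn_cn": int(((s == 0) & (v == 0)).sum()),
                "sn_cy": int(((s == 0) & (v == 1)).sum()),
                "sy_cn": int(((s == 1) & (v == 0)).sum()),
            }
        )

    if not cols:
        return _cells(pairs).to_frame().T.assign(
            n_pairs=lambda d: d.sum(axis=1)
        )
    out = pairs.groupby(cols, sort=True, observed=True).apply(_cells, include_groups=False)
    out = out.reset_index()
    out["n_pairs"] = out[["sy_cy", "sn_cn", "sn_cy", "sy_cn"]].sum(axis=1)
    return out


def accuracy(counts) -> float:
    """(sy_cy + sn_cn) / total; NaN when there are no pairs."""
    c = _as_counts(counts)
    return (c.sy_cy + c.sn_cn) / c.total if c.total > 0 else float("nan")


def sensitivity(counts) -> float:
    """sy_cy / (sy_cy + sy_cn), i.e. TP/(TP+FN); NaN with no scientist-positives."""
    c = _as_counts(counts)
    denom = c.sy_cy + c.sy_cn
    return c.sy_cy / denom if denom > 0 else float("nan")


def specificity(counts) -> float:
    """sn_cn / (sn_cn + sn_cy), i.e. TN/(TN+FP); NaN with no scientist-negatives."""
    c = _as_counts(counts)
    denom = c.sn_cn + c.sn_cy
    return c.sn_cn / denom if denom > 0 else float("nan")


def _as_counts(counts) -> ConfusionCounts:
    if isinstance(counts, ConfusionCounts):
        return counts
    if isinstance(counts, pd.Series) or isinstance(counts, dict):
        return ConfusionCounts(
            int(counts["sy_cy"]), int(counts["sn_cn"]),
            int(counts["sn_cy"]), int(counts["sy_cn"]),
        )
    raise TypeError(f"cannot interpret {type(counts).__name__} as confusion counts")


def agreement_metrics(counts_table: pd.DataFrame) -> pd.DataFrame:
    """Attach accuracy/sensitivity/specificity columns to a counts table."""
    out = counts_table.copy()
    out["accuracy"] = [accuracy(r) for _, r in counts_table.iterrows()]
    out["sensitivity"] = [sensitivity(r) for _, r in counts_table.iterrows()]
    out["specificity"] = [specificity(r) for _, r in counts_table.iterrows()]
    return out


def validate_observers(
    records: pd.DataFrame,
    stratify_by: list[str] | None = None,
    collapse: str = "any",
) -> pd.DataFrame:
    """Full chain: pair, tabulate, and compute the three agreement metrics."""
    pairs, _ = pair_reports(records, collapse=collapse)
    if len(pairs) == 0:
        raise ValueError("no scientist-volunteer pairs found in the records")
    return agreement_metrics(tabulate(pairs, stratify_by))


def percent_cells(counts) -> dict[str, float]:
    """Confusion cells as percentages of the stratum total (figure-style)."""
    c = _as_counts(counts)
    if c.total == 0:
        return {k: float("nan") for k in ("sy_cy", "sn_cn", "sn_cy", "sy_cn")}
    return {
        "sy_cy": 100.0 * c.sy_cy / c.total,
        "sn_cn": 100.0 * c.sn_cn / c.total,
        "sn_cy": 100.0 * c.sn_cy / c.total,
        "sy_cn": 100.0 * c.sy_cn / c.total,
    }
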
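"""Dietary metrics and graphical feeding-strategy classification.

For a prey table of S samples and T items with read counts n_{i,k}:

* **%FOO_i** = 100/S * sum_k I(n_{i,k} > 0) — frequency of occurrence,
  how widespread an item is across samples.
* **%RRA_i** = 100/S * sum_k n_{i,k} / sum_j n_{j,k} — relative read
  abundance, the mean within-sample read share of the item. Each sample
  contributes equally, so RRA is invariant to sequencing-depth
  differences and sums to 100 over items.
* **%P_i** (prey-specific abundance) = 100 * (reads of item i, summed
  over all samples) / (total reads of the samples where item i occurs).
  Restricting the denominator to occupied samples makes %P_i the pooled
  read share "given presence" — the vertical axis of the Costello
  feeding-strategy diagram.

The Costello diagram plots %P_i against %FOO_i. Quadrants (cutlines at
50% on both axes by convention) read as: upper right = dominant prey,
lower left = rare prey, upper left = specialisation by a subset of
individuals (high between-phenotype component of niche width), lower
right = generalised use by most individuals (high within-phenotype
component).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .io import PreyTable, ValidationError

COSTELLO_REGIONS = ("dominant", "rare", "specialist_bpc", "generalist_wpc")


def compute_foo(prey: PreyTable) -> pd.DataFrame:
    """Occurrence count and %FOO per item (index = item)."""
    present = prey.counts.to_numpy() > 0
    occ = present.sum(axis=0)
    return pd.DataFrame(
        {
            "occurrence_count": occ.astype(int),
            "pct_foo": 100.0 * occ / prey.n_samples,
        },
        index=pd.Index(prey.items, name="item"),
    )


def compute_rra(prey: PreyTable) -> pd.Series:
    """%RRA per item: mean across samples of within-sample read share."""
    counts = prey.counts.to_numpy(dtype=float)
    sample_totals = counts.sum(axis=1, keepdims=True)
    if np.any(sample_totals == 0):
        raise ValidationError("sample with zero prey reads reached compute_rra")
    shares = counts / sample_totals
    return pd.Series(
        100.0 * shares.mean(axis=0), index=pd.Index(prey.items, name="item"), name="pct_rra"
    )


def compute_prey_specific_abundance(prey: PreyTable) -> pd.Series:
    """%P_i per item; NaN for an item with zero occurrences."""
    counts = prey.counts.to_numpy(dtype=float)
    sample_totals = counts.sum(axis=1)
    out = np.full(prey.n_items, np.nan)
    for i in range(prey.n_items):
        occupied = counts[:, i] > 0
        if occupied.any():
            out[i] = 100.0 * counts[occupied, i].sum() / sample_totals[occupied].sum()
    return pd.Series(out, index=pd.Index(prey.items, name="item"), name="pct_prey_specific")


def costello_classify(pct_foo: float, pct_prey_specific: float, cutline: float = 50.0) -> str:
    """Quadrant of the Costello diagram, ties (>=) going up/right."""
    for name, v in (("pct_foo", pct_foo), ("pct_prey_specific", pct_prey_specific)):
        if not 0.0 <= v <= 100.0:
            raise ValidationError(f"{name} must be in [0, 100], got {v}")
    hi_p = pct_prey_specific >= cutline
    hi_f = pct_foo >= cutline
    if hi_p and hi_f:
        return "dominant"
    if hi_p:
        return "specialist_bpc"
    if hi_f:
        return "generalist_wpc"
    return "rare"


def metrics_report(prey: PreyTable, cutline: float = 50.0) -> pd.DataFrame:
    """Per-item dietary metrics table, sorted by %RRA descending.

    Items with zero occurrences (possible only on hand-built tables;
    the filter pipeline never emits them) are excluded.
    """
    foo = compute_foo(prey)
    rra = compute_rra(prey)
    psa = compute_prey_specific_abundance(prey)
    df = pd.DataFrame(
        {
            "item": prey.items,
            "prey_group": [prey.groups[i] for i in prey.items],
            "occurrence_count": foo["occurrence_count"].to_numpy(),
            "pct_foo": foo["pct_foo"].to_numpy(),
            "pct_rra": rra.to_numpy(),
            "pct_prey_specific": psa.to_numpy(),
        }
    )
    df = df[df["occurrence_count"] > 0].reset_index(drop=True)
    df["costello_region"] = [
        costello_classify(f, p, cutline)
        for f, p in zip(df["pct_foo"], df["pct_prey_specific"])
    ]
    return df.sort_values("pct_rra", ascending=False, kind="mergesort").reset_index(drop=True)


def plot_costello(report: pd.DataFrame, path: str | Path, cutline: float = 50.0) -> None:
    """Scatter of %P_i against %FOO_i with the quadrant cutlines."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for group, sub in report.groupby("prey_group"):
        ax.scatter(sub["pct_foo"], sub["pct_prey_specific"], label=group, s=30)
    ax.axhline(cutline, color="grey", lw=0.8, ls="--")
    ax.axvline(cutline, color="grey", lw=0.8, ls="--")
    ax.set_xlim(0, 100)
    ax.set_ylim(0, 100)
    ax.set_xlabel("%FOO")
    ax.set_ylabel("prey-specific abundance (%P)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
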
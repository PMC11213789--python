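"""Tabular and graphical diagnostics of an observer study.

Three views summarize agreement visually:

* rank-spread boxplots — per scan, the spread of the ranks assigned by
  the observer panel, sorted by median rank and colored by the median
  Likert score (tight boxes = high interobserver agreement; the color
  shows how coarsely the Likert scale resolves the same ordering);
* Likert confusion matrices — per observer pair (inter) or per observer
  across repeated sessions (intra); a diagonal table is perfect
  agreement;
* repeated-rank plots — per observer, the two ranks each original scan
  received in the two sessions, joined by a line.

Plots are views; the emitted CSV tables are the record.  Every number
in a figure is reproducible from its CSV twin, and table output is
byte-deterministic for fixed inputs.
"""

from __future__ import annotations

import itertools
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import seaborn as sns

from .errors import AlignmentError, ValidationError
from .icc import RatingsMatrix, confusion_matrix

__all__ = ["rank_spread_table", "repeated_rank_table", "render_report"]


def rank_spread_table(
    ranks: RatingsMatrix, likert: RatingsMatrix
) -> pd.DataFrame:
    """Per-scan rank summaries over observers, sorted by median rank.

    Columns: scan_id, median_rank, q1, q3, min, max, median_likert.
    Whiskers are min/max over the panel (no outlier rule — with a
    handful of observers Tukey fences are unstable).
    """
    if set(ranks.subject_ids) != set(likert.subject_ids):
        raise AlignmentError(
            "rank and Likert matrices cover different scans",
            difference=set(ranks.subject_ids) ^ set(likert.subject_ids),
        )
    lik = likert.to_frame()
    rows = []
    for scan, row in ranks.to_frame().iterrows():
        v = row.to_numpy()
        rows.append({
            "scan_id": scan,
            "median_rank": float(np.median(v)),
            "q1": float(np.percentile(v, 25)),
            "q3": float(np.percentile(v, 75)),
            "min": float(v.min()),
            "max": float(v.max()),
            "median_likert": float(np.median(lik.loc[scan].to_numpy())),
        })
    return (
        pd.DataFrame(rows)
        .sort_values(["median_rank", "scan_id"], kind="stable")
        .reset_index(drop=True)
    )


def repeated_rank_table(intra: RatingsMatrix) -> pd.DataFrame:
    """Per-scan (rank_1, rank_2, median/mean) from a n x 2 repeat matrix."""
    if intra.n_raters != 2:
        raise ValidationError("repeated-rank table needs exactly 2 sessions")
    df = intra.to_frame()
    out = pd.DataFrame({
        "scan_id": df.index,
        "rank_1": df.iloc[:, 0].to_numpy(),
        "rank_2": df.iloc[:, 1].to_numpy(),
    })
    out["median_rank"] = out[["rank_1", "rank_2"]].median(axis=1)
    out["mean_rank"] = out[["rank_1", "rank_2"]].mean(axis=1)
    return out.sort_values(["median_rank", "scan_id"], kind="stable").reset_index(drop=True)


def _boxplot_figure(table: pd.DataFrame, ranks: RatingsMatrix, title: str, path: Path):
    order = table.scan_id.tolist()
    df = ranks.to_frame().loc[order]
    cmap = plt.get_cmap("viridis")
    fig, ax = plt.subplots(figsize=(max(8, 0.2 * len(order)), 4))
    data = [df.loc[s].to_numpy() for s in order]
    bp = ax.boxplot(data, whis=(0, 100), patch_artist=True, showfliers=False)
    # color by median Likert, binned at 0.5 steps on the 1-5 scale
    for patch, ml in zip(bp["boxes"], table.median_likert):
        binned = round(ml * 2) / 2
        patch.set_facecolor(cmap((binned - 1) / 4))
    ax.set_xlabel("scans sorted by median rank")
    ax.set_ylabel("rank (1 = lowest IQ)")
    ax.set_xticks([])
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def _heatmap_figure(table: pd.DataFrame, title: str, path: Path):
    fig, ax = plt.subplots(figsize=(4, 3.5))
    sns.heatmap(table, annot=True, fmt="d", cbar=False, cmap="Blues", ax=ax)
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def _repeat_figure(table: pd.DataFrame, title: str, path: Path):
    fig, ax = plt.subplots(figsize=(7, 4))
    x = np.arange(len(table))
    for xi, r1, r2 in zip(x, table.rank_1, table.rank_2):
        ax.plot([xi, xi], [r1, r2], color="0.7", lw=1)
    ax.plot(x, table.rank_1, "o", ms=4, label="session 1")
    ax.plot(x, table.rank_2, "o", ms=4, label="session 2")
    ax.set_xlabel("original scans sorted by median rank")
    ax.set_ylabel("rank (1 = lowest IQ)")
    ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def render_report(study, out_dir) -> list[Path]:
    """Write all figures and their CSV twins for a completed study.

    Emits, per dataset: the rank-spread boxplot + table and all pairwise
    observer Likert confusion matrices; per observer: the repeated-rank
    plot + table and the intra-session Likert confusion matrix.  File
    names are deterministic; returns the list of written paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def save_csv(df: pd.DataFrame, name: str) -> None:
        p = out / name
        df.to_csv(p, index=False)
        written.append(p)

    observers = study.observer_ids
    for ds in sorted(study.datasets):
        ranks = study.inter_matrices[(ds, "pc")]
        likert = study.inter_matrices[(ds, "likert")]
        table = rank_spread_table(ranks, likert)
        save_csv(table, f"rank_spread_{ds}.csv")
        fig_path = out / f"rank_spread_{ds}.png"
        _boxplot_figure(table, ranks, f"Rank spread, {ds}-variation dataset", fig_path)
        written.append(fig_path)

        lik = likert.to_frame()
        for o1, o2 in itertools.combinations(observers, 2):
            cm = confusion_matrix(lik[o1].astype(int), lik[o2].astype(int))
            save_csv(
                cm.rename_axis(o1).reset_index(),
                f"confusion_{ds}_{o1}_vs_{o2}.csv",
            )
            fig_path = out / f"confusion_{ds}_{o1}_vs_{o2}.png"
            _heatmap_figure(cm, f"Likert {ds}: {o1} vs {o2}", fig_path)
            written.append(fig_path)

    for obs in observers:
        table = repeated_rank_table(study.intra_matrices[(obs, "pc")])
        save_csv(table, f"repeated_rank_{obs}.csv")
        fig_path = out / f"repeated_rank_{obs}.png"
        _repeat_figure(table, f"Repeated ranks, {obs}", fig_path)
        written.append(fig_path)

        lm = study.intra_matrices[(obs, "likert")].to_frame()
        cm = confusion_matrix(lm.session1.astype(int), lm.session2.astype(int))
        save_csv(cm.rename_axis("session1").reset_index(), f"confusion_repeat_{obs}.csv")
        fig_path = out / f"confusion_repeat_{obs}.png"
        _heatmap_figure(cm, f"Likert repeat: {obs}", fig_path)
        written.append(fig_path)

    return written
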
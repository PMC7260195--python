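"""Batch annotation workflow: plot pre-generation, tag store, manual routing.

Replaces an interactive review GUI with a batch-friendly equivalent:
one small raster image is pre-generated per (sample, gate) so a
reviewer can page through a whole batch quickly; quality tags are
appended to a CSV-backed store (latest tag wins per sample/gate pair);
and the tag summary computes which samples and populations get routed
back to manual re-gating — the hand-off point of the hybrid workflow.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from cytogate.gating import GateNode, PopulationResult
from cytogate.io import EventMatrix

TAGS = ("good", "bad", "needs_manual_refinement", "low_cell_count")
#: tags that route a (sample, gate) pair to manual re-gating
MANUAL_TAGS = ("bad", "needs_manual_refinement")

STORE_COLUMNS = ["sample_id", "gate_alias", "tag", "analyst", "timestamp"]


@dataclass
class AnnotationRecord:
    sample_id: str
    gate_alias: str
    tag: str
    analyst: str
    timestamp: str


class AnnotationStore:
    """Append-only store of quality tags with latest-wins semantics.

    Persisted as a plain CSV (``sample_id,gate_alias,tag,analyst,
    timestamp``) so any spreadsheet or script can edit it; reloading the
    file reproduces the in-memory effective view exactly (file order is
    authoritative for ties).
    """

    def __init__(self, records: list[AnnotationRecord] | None = None):
        self.records: list[AnnotationRecord] = list(records or [])

    def record(self, sample_id: str, gate_alias: str, tag: str,
               analyst: str = "", timestamp: str | None = None) -> AnnotationRecord:
        if tag not in TAGS:
            raise ValueError(f"unknown tag {tag!r}; allowed: {list(TAGS)}")
        if timestamp is None:
            timestamp = _dt.datetime.now(_dt.timezone.utc).isoformat(timespec="seconds")
        rec = AnnotationRecord(str(sample_id), str(gate_alias), tag,
                               analyst, timestamp)
        self.records.append(rec)
        return rec

    def effective(self) -> dict[tuple[str, str], str]:
        """Latest tag per (sample_id, gate_alias) pair."""
        view: dict[tuple[str, str], str] = {}
        for rec in self.records:
            view[(rec.sample_id, rec.gate_alias)] = rec.tag
        return view

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [[r.sample_id, r.gate_alias, r.tag, r.analyst, r.timestamp]
             for r in self.records],
            columns=STORE_COLUMNS)

    def save(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def load(cls, path: str | Path) -> "AnnotationStore":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        missing = set(STORE_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"annotation CSV missing columns: {sorted(missing)}")
        store = cls()
        for rec in df.itertuples(index=False):
            if rec.tag not in TAGS:
                raise ValueError(f"unknown tag {rec.tag!r} in {path}")
            store.records.append(AnnotationRecord(*rec))
        return store


def _placeholder(ax, alias, error):
    ax.text(0.5, 0.55, f"gate {alias!r} failed", ha="center", va="center",
            fontsize=11, transform=ax.transAxes)
    ax.text(0.5, 0.4, str(error), ha="center", va="center", fontsize=7,
            wrap=True, transform=ax.transAxes, color="firebrick")
    ax.set_xticks([])
    ax.set_yticks([])


def pregenerate_plots(
    m: EventMatrix,
    results: dict[str, PopulationResult],
    nodes: dict[str, GateNode],
    outdir: str | Path,
    hexbin_threshold: int = 50_000,
) -> list[Path]:
    """Write one PNG per fitted gate: ``<sample_id>__<alias>.png``.

    Each image shows the parent population on the gate's dimensions with
    the fitted geometry overlaid: a scatter (hexbin above
    ``hexbin_threshold`` events) for 2D gates, a density trace with the
    cut line for 1D gates.  Errored gates get a placeholder stamped with
    the error.  Images are capped at 480 x 480 px to keep a large batch
    light; re-runs overwrite deterministically.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    for alias, node in nodes.items():
        path = outdir / f"{m.sample_id}__{alias}.png"
        fig, ax = plt.subplots(figsize=(4.8, 4.8), dpi=100)
        try:
            if node.error is not None or node.geometry is None:
                _placeholder(ax, alias, node.error)
            else:
                _plot_gate(ax, m, results, node, hexbin_threshold)
            ax.set_title(f"{m.sample_id} / {alias}", fontsize=9)
            fig.savefig(path)
            written.append(path)
        finally:
            plt.close(fig)
    return written


def _plot_gate(ax, m, results, node, hexbin_threshold):
    parent_res = results.get(node.parent)
    pmask = (parent_res.membership if parent_res is not None
             and parent_res.membership is not None
             else np.ones(m.n_events, dtype=bool))
    geom = node.geometry

    if node.kind == "mindensity":
        from scipy.stats import gaussian_kde
        x = m.column(geom["channel"])[pmask]
        if np.ptp(x) > 0 and x.size >= 2:
            grid = np.linspace(x.min(), x.max(), 256)
            ax.plot(grid, gaussian_kde(x, bw_method="silverman")(grid), lw=1)
        ax.axvline(geom["cut"], color="firebrick", lw=1)
        ax.set_xlabel(geom["channel"], fontsize=8)
        ax.set_ylabel("density", fontsize=8)
        return

    if node.kind == "kmeans_subsets":
        chx, chy = geom["markers"][0], geom["markers"][1]
    elif node.kind in ("quadrant", "rect", "singlet"):
        chx, chy = geom["channels"][0], geom["channels"][1]
    else:  # boolean and friends: no natural plane; show parent size only
        ax.text(0.5, 0.5, f"{node.kind} gate", ha="center", va="center",
                transform=ax.transAxes)
        ax.set_xticks([])
        ax.set_yticks([])
        return

    x = m.column(chx)[pmask]
    y = m.column(chy)[pmask]
    if x.size > hexbin_threshold:
        ax.hexbin(x, y, gridsize=80, cmap="viridis", mincnt=1)
    else:
        ax.plot(x, y, ".", ms=1, alpha=0.4)
    ax.set_xlabel(chx, fontsize=8)
    ax.set_ylabel(chy, fontsize=8)

    if node.kind == "quadrant":
        cx, cy = geom["center"]
        ax.axvline(cx, color="firebrick", lw=1)
        ax.axhline(cy, color="firebrick", lw=1)
    elif node.kind == "rect":
        x1, x2 = geom["x_range"]
        y1, y2 = geom["y_range"]
        ax.plot([x1, x2, x2, x1, x1], [y1, y1, y2, y2, y1],
                color="firebrick", lw=1)
    elif node.kind == "singlet":
        beta, hw = geom["slope"], geom["half_width"]
        gx = np.linspace(x.min(), x.max(), 2)
        ax.plot(gx, beta * gx + hw, color="firebrick", lw=1)
        ax.plot(gx, beta * gx - hw, color="firebrick", lw=1)


def summarize_tags(store: AnnotationStore,
                   sample_ids: list[str] | None = None) -> dict:
    """Compute per-gate and global manual-routing fractions.

    For each gate alias: the fraction of reviewed samples whose
    effective tag is "bad" or "needs_manual_refinement".  Globally: the
    fraction of samples (of ``sample_ids`` if given, else all annotated
    samples) carrying at least one such tag.  Returns a dict with keys
    ``per_gate`` (alias -> {fraction, n_reviewed, n_flagged}),
    ``global_fraction``, ``flagged`` (list of (sample_id, alias) pairs
    for the manual hand-off) and ``unreviewed_gates``.
    """
    view = store.effective()
    if not view:
        raise ValueError("annotation store is empty")

    annotated_samples = {s for s, _ in view}
    universe = [str(s) for s in sample_ids] if sample_ids is not None \
        else sorted(annotated_samples)
    aliases = sorted({a for _, a in view})

    per_gate = {}
    flagged: list[tuple[str, str]] = []
    for alias in aliases:
        tags = {s: t for (s, a), t in view.items() if a == alias}
        n_flag = sum(1 for t in tags.values() if t in MANUAL_TAGS)
        per_gate[alias] = {
            "fraction": n_flag / len(tags) if tags else 0.0,
            "n_reviewed": len(tags),
            "n_flagged": n_flag,
        }
        flagged.extend((s, alias) for s, t in sorted(tags.items())
                       if t in MANUAL_TAGS)

    flagged_samples = {s for s, _ in flagged}
    global_fraction = (sum(1 for s in universe if s in flagged_samples)
                       / len(universe)) if universe else 0.0
    return {
        "per_gate": per_gate,
        "global_fraction": global_fraction,
        "flagged": sorted(flagged),
        "unreviewed_gates": [],
    }


def write_flagged_csv(summary: dict, path: str | Path) -> pd.DataFrame:
    df = pd.DataFrame(summary["flagged"], columns=["sample_id", "gate_alias"])
    df.to_csv(path, index=False)
    return df
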
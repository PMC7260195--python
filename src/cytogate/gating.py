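"""Template-driven hierarchical gating.

A gating strategy lives in a plain CSV template, one row per population:

    alias,parent,dims,method,sign,args
    nondebris,root,FSC-A,mindensity,+,min_peak_height=0.05
    lymph,nondebris,FSC-A|SSC-A,rect,,x_range=[30000,120000];y_range=[0,60000]
    singlets,lymph,FSC-A|FSC-H,singlet,,band_k=4
    Tcell,singlets,CD3|CD19,quadrant,+-,

Rows are applied top-down; each fitted gate (a 1D density-valley cut, a
quadrant split, a rectangle, a doublet-exclusion band, a boolean
combination, or a k-means subset call) intersects its parent's event
mask, yielding per-population memberships, counts, percent-of-parent and
(when a white-blood-cell count is supplied) absolute counts in
10^9 cells/L.  A failed gate never aborts the sample: the affected
subtree is tagged for manual refinement instead, mirroring the hybrid
automated/manual hand-off this package implements.
"""

from __future__ import annotations

import json
import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from scipy.stats import gaussian_kde

from cytogate.io import EventMatrix

logger = logging.getLogger(__name__)

METHODS = {"mindensity", "quadrant", "rect", "singlet", "boolean", "kmeans_subsets"}

#: minimum events required to fit a data-driven gate
MIN_EVENTS = 20


class TemplateError(ValueError):
    """Raised on a malformed gating template."""


class GateError(RuntimeError):
    """A gate could not be fitted; the population is routed to manual review."""

    tag = "needs_manual_refinement"


class LowCellCountError(GateError):
    """Too few parent events to fit a data-driven gate."""

    tag = "low_cell_count"


@dataclass
class TemplateRow:
    alias: str
    parent: str
    dims: list[str]
    method: str
    sign: str
    args: dict


@dataclass
class GatingTemplate:
    rows: list[TemplateRow]

    def __iter__(self):
        return iter(self.rows)

    def __len__(self):
        return len(self.rows)


@dataclass
class GateNode:
    """Fitted gate geometry for one template row on one sample."""

    alias: str
    parent: str
    kind: str
    geometry: dict | None
    error: str | None = None


@dataclass
class PopulationResult:
    alias: str
    parent: str
    membership: np.ndarray | None
    count: int = 0
    pct_of_parent: float = 0.0
    pct_of_total: float = 0.0
    abs_count: float | None = None
    error: str | None = None
    flags: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Template parsing
# ---------------------------------------------------------------------------

_LIST_RE = re.compile(r"^\[.*\]$")


def _parse_arg_value(raw: str):
    raw = raw.strip()
    if _LIST_RE.match(raw):
        return [_parse_arg_value(p) for p in raw[1:-1].split(",") if p.strip()]
    try:
        f = float(raw)
        return int(f) if f.is_integer() and "." not in raw and "e" not in raw.lower() else f
    except ValueError:
        return raw


def parse_args_field(text: str) -> dict:
    """Parse ``key=value;key=value`` args; bracketed lists and numbers are typed."""
    args: dict = {}
    for part in str(text).split(";"):
        part = part.strip()
        if not part:
            continue
        key, eq, val = part.partition("=")
        if not eq:
            raise TemplateError(f"malformed args entry {part!r} (expected key=value)")
        args[key.strip()] = _parse_arg_value(val)
    return args


def parse_template(path: str | Path) -> GatingTemplate:
    """Parse and validate a CSV gating template.

    Columns ``alias,parent,dims,method,sign,args``; ``dims`` is one or
    two channel names joined by ``|``; ``args`` is ``key=value`` pairs
    joined by ``;``.  Rows must be in topological order (each parent is
    ``root`` or declared on an earlier row) with unique aliases.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"alias", "parent", "dims", "method"}
    missing = required - set(df.columns)
    if missing:
        raise TemplateError(f"template missing columns: {sorted(missing)}")

    rows: list[TemplateRow] = []
    seen = {"root"}
    for k, rec in enumerate(df.itertuples(), start=1):
        alias = rec.alias.strip()
        parent = rec.parent.strip()
        method = rec.method.strip()
        if not alias:
            raise TemplateError(f"empty alias at row {k}")
        if alias in seen:
            raise TemplateError(f"duplicate alias {alias!r} at row {k}")
        if method not in METHODS:
            raise TemplateError(f"unknown method {method!r} at row {k}")
        if parent not in seen:
            raise TemplateError(f"orphan parent {parent!r} at row {k}")
        dims = [d.strip() for d in rec.dims.split("|") if d.strip()]
        sign = getattr(rec, "sign", "").strip() if "sign" in df.columns else ""
        args = parse_args_field(getattr(rec, "args", "")) if "args" in df.columns else {}
        if method == "mindensity" and len(dims) != 1:
            raise TemplateError(f"mindensity needs exactly 1 dim at row {k}")
        if method in ("quadrant", "rect", "singlet") and len(dims) != 2:
            raise TemplateError(f"{method} needs exactly 2 dims at row {k}")
        if method == "quadrant" and sign not in {"++", "+-", "-+", "--"}:
            raise TemplateError(f"quadrant sign must be two of +/- at row {k}")
        if method == "mindensity" and sign not in {"+", "-"}:
            raise TemplateError(f"mindensity sign must be + or - at row {k}")
        rows.append(TemplateRow(alias, parent, dims, method, sign, args))
        seen.add(alias)
    return GatingTemplate(rows)


# ---------------------------------------------------------------------------
# Gate fitting primitives
# ---------------------------------------------------------------------------

GRID_POINTS = 512


def _kde_on_grid(x: np.ndarray, gate_range, bandwidth):
    lo, hi = gate_range
    inside = x[(x >= lo) & (x <= hi)]
    if inside.size < MIN_EVENTS:
        raise LowCellCountError(
            f"only {inside.size} events in gate_range [{lo:g},{hi:g}] "
            f"(minimum {MIN_EVENTS})"
        )
    if np.ptp(inside) == 0:
        raise GateError("degenerate data: all events identical in gate_range")
    bw = "silverman" if bandwidth in (None, "auto") else float(bandwidth)
    kde = gaussian_kde(inside, bw_method=bw)
    grid = np.linspace(lo, hi, GRID_POINTS)
    dens = kde(grid)
    return grid, dens


def _detect_peaks(dens: np.ndarray, min_peak_height: float) -> list[int]:
    thresh = min_peak_height * dens.max()
    idx, _ = find_peaks(dens, height=thresh)
    peaks = list(idx)
    # boundary maxima count as peaks (a mode clipped by gate_range)
    if dens[0] > dens[1] and dens[0] >= thresh:
        peaks.insert(0, 0)
    if dens[-1] > dens[-2] and dens[-1] >= thresh:
        peaks.append(len(dens) - 1)
    return peaks


def density_cut_1d(x: np.ndarray, args: dict | None = None) -> float:
    """Place a 1D cut point by kernel-density valley finding.

    A Gaussian KDE (Silverman bandwidth unless ``bandwidth`` is given) is
    evaluated on a 512-point grid over ``gate_range`` (default: the data
    range).  Local maxima at height >= ``min_peak_height`` x the global
    maximum count as peaks.  With two or more peaks the cut is the
    density minimum between the two tallest (ties: leftmost pair,
    leftmost valley).  With a single peak the cut sits where the density
    falls to ``min_peak_height`` x the peak height on the side given by
    ``sign`` ("+": right shoulder, "-": left shoulder).  Deterministic
    for fixed input.

    Raises
    ------
    LowCellCountError
        Fewer than 20 events in range.
    GateError
        No peak clears the height threshold.
    """
    args = args or {}
    x = np.asarray(x, dtype=np.float64)
    if x.size < MIN_EVENTS:
        raise LowCellCountError(f"only {x.size} events (minimum {MIN_EVENTS})")
    gate_range = args.get("gate_range") or (float(x.min()), float(x.max()))
    min_peak_height = float(args.get("min_peak_height", 0.05))
    grid, dens = _kde_on_grid(x, gate_range, args.get("bandwidth"))

    peaks = _detect_peaks(dens, min_peak_height)
    if not peaks:
        raise GateError("no density peaks above min_peak_height")
    expected = args.get("expected_peaks")
    if expected is not None and len(peaks) < int(expected):
        warnings.warn(
            f"found {len(peaks)} density peaks, expected {expected}",
            stacklevel=2,
        )

    if len(peaks) >= 2:
        # two tallest; equal heights resolve to the leftmost pair
        order = sorted(peaks, key=lambda i: (-dens[i], i))
        p1, p2 = sorted(order[:2])
        between = slice(p1, p2 + 1)
        cut_idx = p1 + int(np.argmin(dens[between]))
        return float(grid[cut_idx])

    peak = peaks[0]
    thresh = min_peak_height * dens[peak]
    sign = args.get("sign", "+")
    if sign == "+":
        after = np.nonzero(dens[peak:] <= thresh)[0]
        cut_idx = peak + int(after[0]) if after.size else GRID_POINTS - 1
    else:
        before = np.nonzero(dens[: peak + 1] <= thresh)[0]
        cut_idx = int(before[-1]) if before.size else 0
    return float(grid[cut_idx])


def quadrant_gate(x: np.ndarray, y: np.ndarray, args: dict | None = None):
    """Fit a quadrant gate: independent 1D density cuts on each axis.

    Returns ``((cx, cy), masks)`` where ``masks`` maps the four sign
    pairs ``"++", "+-", "-+", "--"`` (x sign then y sign) to boolean
    memberships.  The four quadrants partition the input exactly:
    "+" means strictly above the cut, "-" means at or below.
    """
    args = args or {}

    def axis_args(suffix):
        a = {k: v for k, v in args.items() if not k.endswith(("_x", "_y"))}
        for k, v in args.items():
            if k.endswith(f"_{suffix}"):
                a[k[:-2]] = v
        a.setdefault("sign", "+")
        return a

    cx = density_cut_1d(x, axis_args("x"))
    cy = density_cut_1d(y, axis_args("y"))
    xp, yp = x > cx, y > cy
    masks = {
        "++": xp & yp,
        "+-": xp & ~yp,
        "-+": ~xp & yp,
        "--": ~xp & ~yp,
    }
    return (cx, cy), masks


def singlet_gate(a: np.ndarray, h: np.ndarray, args: dict | None = None):
    """Doublet exclusion on the FSC-A/FSC-H plane.

    Doublets carry roughly double the area signal but a sub-additive
    height, so they fall below the singlet diagonal.  A robust line
    h ~ beta * a through the origin is fitted with beta = median(h/a);
    events within ``band_k`` sigma-consistent MADs (1.4826 x raw MAD) of
    the residuals are kept (``band_k`` defaults to 4, i.e. a ~4-sigma
    band under Gaussian noise).

    Returns ``(membership, geometry)`` with geometry
    ``{"slope", "half_width"}``.
    """
    args = args or {}
    band_k = float(args.get("band_k", 4.0))
    a = np.asarray(a, dtype=np.float64)
    h = np.asarray(h, dtype=np.float64)
    if a.size < MIN_EVENTS:
        raise LowCellCountError(f"only {a.size} events (minimum {MIN_EVENTS})")
    nonzero = a != 0
    if not nonzero.any():
        raise GateError("degenerate scatter: all FSC-A values are zero")
    beta = float(np.median(h[nonzero] / a[nonzero]))
    resid = h - beta * a
    mad = 1.4826 * float(np.median(np.abs(resid - np.median(resid))))
    half_width = band_k * mad
    membership = np.abs(resid) <= half_width
    return membership, {"slope": beta, "intercept": 0.0, "half_width": half_width}


_BOOL_TOKEN = re.compile(r"\s*(?:(?P<name>\w+)|(?P<op>[&|!~()]))")


def _eval_boolean(expr: str, masks: dict[str, np.ndarray], n: int) -> np.ndarray:
    """Evaluate a boolean gate expression over population masks.

    Supports aliases, ``&``, ``|``, ``!``/``~`` and parentheses.
    """
    pos = 0
    py: list[str] = []
    names: dict[str, np.ndarray] = {}
    while pos < len(expr):
        m = _BOOL_TOKEN.match(expr, pos)
        if m is None:
            raise GateError(f"cannot parse boolean expression at {expr[pos:]!r}")
        pos = m.end()
        if m.group("name"):
            name = m.group("name")
            if name not in masks:
                raise GateError(f"boolean expression references unknown population {name!r}")
            key = f"m{len(names)}"
            names[key] = masks[name]
            py.append(key)
        else:
            py.append("~" if m.group("op") == "!" else m.group("op"))
    try:
        result = eval(" ".join(py), {"__builtins__": {}}, names)  # noqa: S307 - sanitized tokens
    except SyntaxError as exc:
        raise GateError(f"malformed boolean expression {expr!r}") from exc
    result = np.asarray(result, dtype=bool)
    if result.shape != (n,):
        raise GateError("boolean expression did not produce an event mask")
    return result


# ---------------------------------------------------------------------------
# Template application
# ---------------------------------------------------------------------------

def _population(alias, parent, membership, parent_count, n_total, wbc, flags=None):
    count = int(membership.sum())
    flags = list(flags or [])
    if parent_count == 0:
        pct_parent = 0.0
        if "low_cell_count" not in flags:
            flags.append("low_cell_count")
    else:
        pct_parent = 100.0 * count / parent_count
    pct_total = 100.0 * count / n_total
    abs_count = (pct_total / 100.0) * wbc if wbc is not None else None
    return PopulationResult(
        alias=alias, parent=parent, membership=membership, count=count,
        pct_of_parent=pct_parent, pct_of_total=pct_total,
        abs_count=abs_count, flags=flags,
    )


def _fail(results, nodes, row, exc):
    tag = getattr(exc, "tag", "needs_manual_refinement")
    logger.warning("gate %s failed: %s", row.alias, exc)
    nodes[row.alias] = GateNode(row.alias, row.parent, row.method, None, error=str(exc))
    results[row.alias] = PopulationResult(
        alias=row.alias, parent=row.parent, membership=None,
        error=str(exc), flags=[tag],
    )


def apply_template(
    m: EventMatrix,
    template: GatingTemplate,
    wbc: float | None = None,
    min_events: int = MIN_EVENTS,
    seed: int = 0,
) -> tuple[dict[str, PopulationResult], dict[str, GateNode]]:
    """Apply a gating template to an event matrix.

    Rows are evaluated in template order; each gate is fitted on the
    parent population's events and the child mask is intersected with
    the parent mask.  ``kmeans_subsets`` rows delegate to
    :mod:`cytogate.subsets`.  A failed gate tags its whole subtree
    ("needs_manual_refinement" or "low_cell_count") rather than aborting
    the sample.

    Returns ``(results, nodes)``: population results and fitted gate
    geometry keyed by alias (including ``"root"`` in results).
    """
    n_total = m.n_events
    root_mask = np.ones(n_total, dtype=bool)
    results: dict[str, PopulationResult] = {
        "root": PopulationResult(
            alias="root", parent="", membership=root_mask, count=n_total,
            pct_of_parent=100.0, pct_of_total=100.0,
            abs_count=wbc if wbc is not None else None,
        )
    }
    nodes: dict[str, GateNode] = {}

    for row in template:
        parent_res = results.get(row.parent)
        if parent_res is None or parent_res.membership is None:
            _fail(results, nodes, row,
                  GateError(f"parent {row.parent!r} unavailable (upstream gate failed)"))
            continue
        for dim in row.dims:
            if dim not in m.channels:
                _fail(results, nodes, row, GateError(f"channel {dim!r} not in sample"))
                break
        else:
            try:
                _apply_row(m, row, parent_res, results, nodes, n_total, wbc,
                           min_events, seed)
            except GateError as exc:
                _fail(results, nodes, row, exc)
            except Exception as exc:  # isolate any per-gate failure
                _fail(results, nodes, row, GateError(str(exc)))
    return results, nodes


def _apply_row(m, row, parent_res, results, nodes, n_total, wbc, min_events, seed):
    pmask = parent_res.membership
    pcount = parent_res.count

    if row.method in ("mindensity", "quadrant", "rect", "singlet") and pcount < min_events:
        raise LowCellCountError(
            f"parent {row.parent!r} has {pcount} events (minimum {min_events})"
        )

    if row.method == "mindensity":
        x = m.column(row.dims[0])[pmask]
        args = dict(row.args, sign=row.sign)
        c = density_cut_1d(x, args)
        local = x > c if row.sign == "+" else x <= c
        membership = pmask.copy()
        membership[pmask] = local
        nodes[row.alias] = GateNode(row.alias, row.parent, "mindensity",
                                    {"channel": row.dims[0], "cut": c, "sign": row.sign})
        results[row.alias] = _population(row.alias, row.parent, membership,
                                         pcount, n_total, wbc)

    elif row.method == "quadrant":
        x = m.column(row.dims[0])[pmask]
        y = m.column(row.dims[1])[pmask]
        (cx, cy), masks = quadrant_gate(x, y, row.args)
        local = masks[row.sign]
        membership = pmask.copy()
        membership[pmask] = local
        nodes[row.alias] = GateNode(
            row.alias, row.parent, "quadrant",
            {"channels": row.dims, "center": [cx, cy], "quadrant": row.sign})
        results[row.alias] = _population(row.alias, row.parent, membership,
                                         pcount, n_total, wbc)

    elif row.method == "rect":
        xr = row.args.get("x_range")
        yr = row.args.get("y_range")
        if xr is None or yr is None:
            raise GateError("rect gate requires x_range and y_range args")
        xr = [float(v) for v in xr]
        yr = [float(v) for v in yr]
        x = m.column(row.dims[0])
        y = m.column(row.dims[1])
        membership = pmask & (x >= xr[0]) & (x <= xr[1]) & (y >= yr[0]) & (y <= yr[1])
        nodes[row.alias] = GateNode(row.alias, row.parent, "rect",
                                    {"channels": row.dims, "x_range": xr, "y_range": yr})
        results[row.alias] = _population(row.alias, row.parent, membership,
                                         pcount, n_total, wbc)

    elif row.method == "singlet":
        a = m.column(row.dims[0])[pmask]
        h = m.column(row.dims[1])[pmask]
        local, geom = singlet_gate(a, h, row.args)
        membership = pmask.copy()
        membership[pmask] = local
        nodes[row.alias] = GateNode(row.alias, row.parent, "singlet",
                                    dict(geom, channels=row.dims))
        results[row.alias] = _population(row.alias, row.parent, membership,
                                         pcount, n_total, wbc)

    elif row.method == "boolean":
        expr = row.args.get("expr")
        if not expr:
            raise GateError("boolean gate requires an expr arg")
        masks = {a: r.membership for a, r in results.items() if r.membership is not None}
        membership = _eval_boolean(expr, masks, n_total) & pmask
        nodes[row.alias] = GateNode(row.alias, row.parent, "boolean", {"expr": expr})
        results[row.alias] = _population(row.alias, row.parent, membership,
                                         pcount, n_total, wbc)

    elif row.method == "kmeans_subsets":
        _apply_kmeans_row(m, row, results, nodes, n_total, wbc, seed)

    else:  # pragma: no cover - parse_template rejects unknown methods
        raise GateError(f"unknown method {row.method!r}")


def _apply_kmeans_row(m, row, results, nodes, n_total, wbc, seed):
    from cytogate.subsets import SUBSET_NAMES, SubsetCallInput, call_subsets

    markers = row.args.get("markers")
    parents = row.args.get("parents")
    if isinstance(markers, str):
        markers = [s.strip() for s in markers.split(",")]
    if isinstance(parents, str):
        parents = [s.strip() for s in parents.split(",")]
    if not markers or len(markers) != 3:
        raise GateError("kmeans_subsets requires args markers=<3 channel names>")
    if not parents or len(parents) != 2:
        raise GateError("kmeans_subsets requires args parents=<2 population aliases>")
    row_seed = int(row.args.get("seed", seed))

    parent_masks = {}
    for p in parents:
        res = results.get(p)
        if res is None or res.membership is None:
            raise GateError(f"kmeans_subsets parent {p!r} unavailable")
        parent_masks[p] = res.membership
    for mk in markers:
        if mk not in m.channels:
            raise GateError(f"kmeans_subsets marker {mk!r} not in sample")

    pooled = parent_masks[parents[0]] | parent_masks[parents[1]]
    idx = np.nonzero(pooled)[0]
    events = np.column_stack([m.column(mk)[idx] for mk in markers])
    parent_label = np.where(parent_masks[parents[0]][idx], parents[0], parents[1])

    call = call_subsets(SubsetCallInput(events=events, parent=parent_label,
                                        parent_names=tuple(parents)), seed=row_seed)

    nodes[row.alias] = GateNode(
        row.alias, row.parent, "kmeans_subsets",
        {"markers": markers, "parents": parents, "seed": row_seed,
         "flagged": call.flagged,
         "cluster_signs": [list(s) for s in call.cluster_signs],
         "subset_labels": list(call.subset_label)})

    for p in parents:
        pres = results[p]
        for subset in SUBSET_NAMES:
            mask = np.zeros(n_total, dtype=bool)
            sel = (parent_label == p) & np.isin(
                call.assignment,
                [c for c, lab in enumerate(call.subset_label) if lab == subset])
            mask[idx[sel]] = True
            alias = f"{p}/{subset}"
            flags = ["needs_manual_refinement"] if call.flagged else []
            results[alias] = _population(alias, p, mask, pres.count,
                                         n_total, wbc, flags=flags)


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def export_gates_json(sample_id: str,
                      nodes: dict[str, GateNode],
                      results: dict[str, PopulationResult],
                      path: str | Path) -> None:
    """Serialize fitted gates and population counts for one sample as JSON."""
    gates = []
    aliases = list(results)
    for alias in aliases:
        res = results[alias]
        node = nodes.get(alias)
        gates.append({
            "alias": alias,
            "parent": res.parent,
            "kind": node.kind if node else ("root" if alias == "root" else "derived"),
            "geometry": node.geometry if node else None,
            "count": res.count if res.error is None else None,
            "pct_of_parent": res.pct_of_parent if res.error is None else None,
            "pct_of_total": res.pct_of_total if res.error is None else None,
            "abs_count": res.abs_count,
            "error": res.error or (node.error if node else None),
            "flags": res.flags,
        })
    doc = {"sample_id": sample_id, "gates": gates}
    Path(path).write_text(json.dumps(doc, indent=2))


def load_gates_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


COUNTS_COLUMNS = ["sample_id", "alias", "count", "pct_of_parent",
                  "pct_of_total", "abs_count"]


def write_counts_csv(batch: list[tuple[str, dict[str, PopulationResult]]],
                     path: str | Path) -> pd.DataFrame:
    """Write one row per sample x population; returns the DataFrame written."""
    rows = []
    for sample_id, results in batch:
        for alias, res in results.items():
            if alias == "root":
                continue
            rows.append({
                "sample_id": sample_id,
                "alias": alias,
                "count": res.count if res.error is None else np.nan,
                "pct_of_parent": res.pct_of_parent if res.error is None else np.nan,
                "pct_of_total": res.pct_of_total if res.error is None else np.nan,
                "abs_count": res.abs_count if res.abs_count is not None else np.nan,
            })
    df = pd.DataFrame(rows, columns=COUNTS_COLUMNS)
    df.to_csv(path, index=False)
    return df
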
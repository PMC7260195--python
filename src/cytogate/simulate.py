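"""Synthetic cytometry data with ground truth.

Generates the statistical structure the pipeline assumes so every
module is testable without instrument data: hierarchical
Gaussian-mixture event clouds (major leukocyte lineages plus the eight
CCR7/CD45RA/CD28 memory/effector T-cell subsets) with per-event truth
labels, doublets with sub-additive FSC-H, dead cells with high
viability-dye signal, paired "automated vs. manual" count perturbations
with a known bias, and replicated-control technician designs with known
variance components.

Fluorescence values are drawn directly in transformed (arcsinh-like)
units, where marker-positive and -negative populations are
well-approximated by Gaussians; scatter channels are in linear units.
All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from cytogate.io import EventMatrix
from cytogate.subsets import SUBSET_NAMES, SubsetCallInput

#: (CCR7, CD45RA, CD28) sign triple per subset
SUBSET_SIGNS = {
    "naive": ("+", "+", "+"),
    "central_memory": ("+", "-", "+"),
    "effector_memory": ("-", "-", "-"),
    "effector": ("-", "+", "-"),
}

#: marker-negative and -positive component (mean, SD) in transformed units;
#: 0 vs 4 at SD 0.5 puts 8 component SDs between the modes.
NEG = (0.0, 0.5)
POS = (4.0, 0.5)


class SpecError(ValueError):
    pass


@dataclass
class PopulationSpec:
    alias: str
    parent: str  # "root" for top level
    fraction: float  # fraction of the parent population
    channel_stats: dict[str, tuple[float, float]] = field(default_factory=dict)


@dataclass
class PanelSpec:
    """Declarative description of a synthetic sample.

    ``populations`` form a tree rooted at "root"; sibling fractions must
    sum to <= 1 (the remainder becomes an unlabelled "other" population
    with the parent's channel statistics).  ``channel_stats`` entries
    override the parent's; unspecified fluorescence channels default to
    the marker-negative component.  ``FSC-H`` is derived from FSC-A via
    ``singlet_slope`` plus noise rather than sampled independently, so
    singlet gating has a real diagonal to find.
    """

    channels: list[str]
    populations: list[PopulationSpec]
    root_stats: dict[str, tuple[float, float]] = field(default_factory=dict)
    n_events: int = 20_000
    doublet_fraction: float = 0.0
    dead_fraction: float = 0.0
    singlet_slope: float = 0.98
    fsc_h_noise: float = 1500.0
    livedead_channel: str = "LiveDead"

    def validate(self) -> None:
        aliases = {"root"}
        for p in self.populations:
            if p.alias in aliases:
                raise SpecError(f"duplicate population alias {p.alias!r}")
            if p.parent not in aliases:
                raise SpecError(f"population {p.alias!r} has undeclared parent {p.parent!r}")
            if not 0 <= p.fraction <= 1:
                raise SpecError(f"fraction of {p.alias!r} outside [0,1]")
            for ch, (_, sd) in p.channel_stats.items():
                if sd <= 0:
                    raise SpecError(f"SD for {ch!r} in {p.alias!r} must be > 0")
            aliases.add(p.alias)
        for parent in {"root"} | {p.alias for p in self.populations}:
            total = sum(p.fraction for p in self.populations if p.parent == parent)
            if total > 1 + 1e-9:
                raise SpecError(f"children of {parent!r} have fractions summing to {total}")
        if not 0 <= self.doublet_fraction < 1 or not 0 <= self.dead_fraction < 1:
            raise SpecError("doublet_fraction and dead_fraction must be in [0,1)")
        if self.n_events < 1:
            raise SpecError("n_events must be positive")


@dataclass
class GroundTruth:
    """Per-event truth for one generated sample."""

    labels: np.ndarray  # full population path per event, "" for debris/other
    is_doublet: np.ndarray
    is_dead: np.ndarray
    true_fractions: dict[str, float]  # alias -> fraction of parent
    wbc: float

    def mask(self, path_prefix: str) -> np.ndarray:
        """Events belonging to a population or any of its descendants."""
        labels = self.labels.astype(str)
        return ((labels == path_prefix)
                | np.char.startswith(labels, path_prefix + "/"))


def default_panel(n_events: int = 20_000, doublet_fraction: float = 0.05,
                  dead_fraction: float = 0.02) -> PanelSpec:
    """A reconstruction of a broad immunophenotyping panel hierarchy.

    Major lineages (T, B, NK cells, monocytes, dendritic cells) under a
    lymphocyte/monocyte scatter split, with the eight
    memory/effector T-cell subsets under CD4/CD8.  Fractions are typical
    peripheral-blood values; marker-positive/negative components sit 8
    component SDs apart so that density gates have clean valleys.
    """
    subs = [("naive", 0.40), ("central_memory", 0.25),
            ("effector_memory", 0.25), ("effector", 0.10)]

    def subset_rows(parent):
        rows = []
        for name, frac in subs:
            stats = {mk: (POS if s == "+" else NEG)
                     for mk, s in zip(("CCR7", "CD45RA", "CD28"),
                                      SUBSET_SIGNS[name])}
            rows.append(PopulationSpec(f"{parent}_{name}", parent, frac, stats))
        return rows

    pops = [
        PopulationSpec("lymph", "root", 0.55,
                       {"FSC-A": (70_000, 9_000), "SSC-A": (20_000, 6_000)}),
        PopulationSpec("Tcell", "lymph", 0.60, {"CD3": POS}),
        PopulationSpec("CD4", "Tcell", 0.60, {"CD4": POS}),
        *subset_rows("CD4"),
        PopulationSpec("CD8", "Tcell", 0.35, {"CD8": POS}),
        *subset_rows("CD8"),
        PopulationSpec("Bcell", "lymph", 0.20,
                       {"CD19": POS, "CD20": POS, "HLA-DR": (3.5, 0.5)}),
        PopulationSpec("NK", "lymph", 0.12, {"CD16": POS, "CD56": POS}),
        PopulationSpec("mono", "root", 0.25,
                       {"FSC-A": (95_000, 10_000), "SSC-A": (45_000, 8_000),
                        "CD14": POS, "HLA-DR": POS, "CD4": (2.0, 0.5)}),
        PopulationSpec("dc", "root", 0.05,
                       {"FSC-A": (85_000, 9_000), "SSC-A": (30_000, 7_000),
                        "HLA-DR": POS}),
    ]
    return PanelSpec(
        channels=["FSC-A", "FSC-H", "SSC-A", "LiveDead", "CD3", "CD19",
                  "CD14", "CD16", "CD56", "CD20", "HLA-DR", "CD4", "CD8",
                  "CCR7", "CD45RA", "CD28"],
        populations=pops,
        root_stats={"FSC-A": (30_000, 8_000), "SSC-A": (12_000, 5_000)},
        n_events=n_events,
        doublet_fraction=doublet_fraction,
        dead_fraction=dead_fraction,
    )


def _leaves_with_labels(spec: PanelSpec):
    """Leaves of the population tree with full path labels, probabilities
    and effective channel stats; an "other" remainder at any node becomes
    a leaf carrying the node's own path and stats."""
    children: dict[str, list[PopulationSpec]] = {}
    for p in spec.populations:
        children.setdefault(p.parent, []).append(p)
    base = {ch: NEG for ch in spec.channels if ch != "FSC-H"}
    base.update(spec.root_stats)
    out = []

    def walk(alias, path, prob, stats):
        kids = children.get(alias, [])
        if not kids:
            out.append((path, prob, stats))
            return
        rest = 1.0 - sum(k.fraction for k in kids)
        for k in kids:
            kstats = dict(stats)
            kstats.update(k.channel_stats)
            kpath = f"{path}/{k.alias}" if path else k.alias
            walk(k.alias, kpath, prob * k.fraction, kstats)
        if rest > 1e-9:
            out.append((path, prob * rest, stats))

    walk("root", "", 1.0, base)
    return out


def generate_sample(spec: PanelSpec, seed: int = 0,
                    sample_id: str = "sim") -> tuple[EventMatrix, GroundTruth]:
    """Draw one synthetic sample from a :class:`PanelSpec`.

    Events are sampled per leaf population from independent Gaussians in
    each channel (FSC-H derived from FSC-A along the singlet diagonal).
    Doublets are synthesized by summing two singlets' scatter signals
    with sub-additive FSC-H (x 0.6) and taking the elementwise max of
    their fluorescence; dead cells get a marker-positive viability-dye
    signal.  Truth labels, doublet/dead masks and the per-population
    target fractions are returned alongside.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    leaves = _leaves_with_labels(spec)
    probs = np.array([p for _, p, _ in leaves])
    probs = probs / probs.sum()

    n = spec.n_events
    n_doublet = int(round(spec.doublet_fraction * n))
    n_single = n - n_doublet
    n_draw = n_single + 2 * n_doublet

    which = rng.choice(len(leaves), size=n_draw, p=probs)
    data = np.empty((n_draw, len(spec.channels)))
    ch_idx = {ch: j for j, ch in enumerate(spec.channels)}
    for li, (_, _, stats) in enumerate(leaves):
        rows = np.nonzero(which == li)[0]
        if rows.size == 0:
            continue
        for ch in spec.channels:
            if ch == "FSC-H":
                continue
            mu, sd = stats.get(ch, NEG)
            data[rows, ch_idx[ch]] = rng.normal(mu, sd, size=rows.size)
    if "FSC-H" in ch_idx:
        data[:, ch_idx["FSC-H"]] = (spec.singlet_slope * data[:, ch_idx["FSC-A"]]
                                    + rng.normal(0, spec.fsc_h_noise, size=n_draw))
    labels = np.array([leaves[w][0] for w in which], dtype=object)

    # fold the last 2*n_doublet draws pairwise into doublets
    singles = data[:n_single]
    single_labels = labels[:n_single]
    if n_doublet:
        d1 = data[n_single:n_single + n_doublet]
        d2 = data[n_single + n_doublet:]
        doublets = np.maximum(d1, d2)
        for ch in ("FSC-A", "SSC-A"):
            if ch in ch_idx:
                doublets[:, ch_idx[ch]] = d1[:, ch_idx[ch]] + d2[:, ch_idx[ch]]
        if "FSC-H" in ch_idx:
            doublets[:, ch_idx["FSC-H"]] = 0.6 * (d1[:, ch_idx["FSC-H"]]
                                                  + d2[:, ch_idx["FSC-H"]])
        all_data = np.vstack([singles, doublets])
        all_labels = np.concatenate([single_labels,
                                     np.array(["doublet"] * n_doublet, dtype=object)])
        is_doublet = np.concatenate([np.zeros(n_single, bool), np.ones(n_doublet, bool)])
    else:
        all_data, all_labels = singles, single_labels
        is_doublet = np.zeros(n_single, bool)

    is_dead = rng.random(n) < spec.dead_fraction
    if spec.livedead_channel in ch_idx:
        all_data[is_dead, ch_idx[spec.livedead_channel]] = rng.normal(
            POS[0], POS[1], size=int(is_dead.sum()))

    perm = rng.permutation(n)
    all_data = all_data[perm]
    all_labels = all_labels[perm]
    is_doublet = is_doublet[perm]
    is_dead = is_dead[perm]

    m = EventMatrix(sample_id=sample_id, channels=list(spec.channels),
                    data=all_data,
                    metadata={"CYT": "cytogate-simulator", "SEED": str(seed)})
    truth = GroundTruth(
        labels=all_labels,
        is_doublet=is_doublet,
        is_dead=is_dead,
        true_fractions={p.alias: p.fraction for p in spec.populations},
        wbc=float(rng.uniform(4.0, 9.0)),
    )
    return m, truth


def generate_tcell_sample(
    fractions: dict[str, tuple[float, float, float, float]] | None = None,
    separation: float = 6.0,
    n_events: int = 20_000,
    cd4_share: float = 0.6,
    seed: int = 0,
) -> tuple[SubsetCallInput, pd.DataFrame]:
    """Generate pooled CD4/CD8 T-cell events in (CCR7, CD45RA, CD28) space.

    Each subset is a spherical unit-SD Gaussian centred at
    +/- separation/2 in each marker dimension according to its sign
    triple, so ``separation`` is the distance between "+" and "-" modes
    in component-SD units (0 collapses all four components onto one
    cloud).  ``fractions`` maps parent -> subset fractions in
    :data:`cytogate.subsets.SUBSET_NAMES` order and must sum to 1 per
    parent.  Returns the call input plus a truth table with columns
    ``parent, subset``.
    """
    if fractions is None:
        fractions = {"CD4": (0.40, 0.25, 0.25, 0.10),
                     "CD8": (0.40, 0.25, 0.25, 0.10)}
    for parent, fr in fractions.items():
        if abs(sum(fr) - 1.0) > 1e-9:
            raise SpecError(f"subset fractions for {parent!r} sum to {sum(fr)}, not 1")
    parents = list(fractions)
    rng = np.random.default_rng(seed)

    n_by_parent = {parents[0]: int(round(cd4_share * n_events))}
    n_by_parent[parents[1]] = n_events - n_by_parent[parents[0]]

    half = separation / 2.0
    rows, parent_lab, subset_lab = [], [], []
    for parent in parents:
        counts = rng.multinomial(n_by_parent[parent], fractions[parent])
        for subset, k in zip(SUBSET_NAMES, counts):
            center = np.array([half if s == "+" else -half
                               for s in SUBSET_SIGNS[subset]])
            rows.append(rng.normal(center, 1.0, size=(k, 3)))
            parent_lab.extend([parent] * k)
            subset_lab.extend([subset] * k)
    events = np.vstack(rows)
    truth = pd.DataFrame({"parent": parent_lab, "subset": subset_lab})

    perm = rng.permutation(len(events))
    events = events[perm]
    truth = truth.iloc[perm].reset_index(drop=True)
    inp = SubsetCallInput(events=events, parent=truth["parent"].to_numpy(),
                          parent_names=tuple(parents))
    return inp, truth


def generate_paired_counts(
    bias: float = 1.0,
    cv_hybrid: float = 0.05,
    cv_manual: float = 0.05,
    n_samples: int = 500,
    mean_value: float = 2.0,
    between_sample_cv: float = 0.3,
    population: str = "pop",
    seed: int = 0,
) -> pd.DataFrame:
    """Paired automated-vs-manual values with a known multiplicative bias.

    Per sample a true value is drawn lognormally around ``mean_value``
    (between-sample CV ``between_sample_cv``); the manual method
    observes it with a mean-one lognormal error of CV ``cv_manual`` and
    the automated method with CV ``cv_hybrid`` after multiplying by
    ``bias`` — so the expected percent bias (ratio of means) is
    ``100 * (bias - 1)``.  With both CVs zero the two methods are
    exactly proportional and the correlation is 1.

    Returns columns ``sample_id, population, hybrid, manual, true``.
    """
    if cv_hybrid < 0 or cv_manual < 0:
        raise SpecError("CVs must be >= 0")
    rng = np.random.default_rng(seed)

    def lognorm_factor(cv, size):
        if cv == 0:
            return np.ones(size)
        s2 = np.log1p(cv ** 2)
        return rng.lognormal(-s2 / 2, np.sqrt(s2), size=size)

    true = mean_value * lognorm_factor(between_sample_cv, n_samples) \
        if between_sample_cv > 0 else np.full(n_samples, mean_value)
    hybrid = bias * true * lognorm_factor(cv_hybrid, n_samples)
    manual = true * lognorm_factor(cv_manual, n_samples)
    return pd.DataFrame({
        "sample_id": [f"s{i:04d}" for i in range(n_samples)],
        "population": population,
        "hybrid": hybrid,
        "manual": manual,
        "true": true,
    })


def generate_technician_study(
    var_inter: float = 0.5,
    var_intra: float = 0.5,
    n_controls: int = 8,
    n_technicians: int = 5,
    n_reps: int = 4,
    baseline: float = 50.0,
    control_sd: float = 5.0,
    population: str = "pop",
    seed: int = 0,
) -> pd.DataFrame:
    """Replicated-control design with known technician variance components.

    value = baseline + control effect (fixed, drawn once per control)
    + technician effect ~ N(0, var_inter) + residual ~ N(0, var_intra),
    fully crossed: every technician measures every control ``n_reps``
    times.  The implied ICC is var_inter / (var_inter + var_intra).
    """
    if var_inter < 0 or var_intra < 0:
        raise SpecError("variance components must be >= 0")
    rng = np.random.default_rng(seed)
    control_eff = rng.normal(0, control_sd, size=n_controls)
    tech_eff = rng.normal(0, np.sqrt(var_inter), size=n_technicians) \
        if var_inter > 0 else np.zeros(n_technicians)
    rows = []
    for c in range(n_controls):
        for t in range(n_technicians):
            resid = rng.normal(0, np.sqrt(var_intra), size=n_reps) \
                if var_intra > 0 else np.zeros(n_reps)
            for r in range(n_reps):
                rows.append({
                    "control_id": f"ctrl{c + 1}",
                    "technician_id": f"tech{t + 1}",
                    "replicate": r + 1,
                    "population": population,
                    "value": baseline + control_eff[c] + tech_eff[t] + resid[r],
                })
    return pd.DataFrame(rows)
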
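"""Hierarchical gating: high-resolution differential cell counts.

The gating tree removes debris, doublets and dead cells, selects CD45+
leukocytes, splits them by side scatter into lymphocytes (SSC low),
monocytes/macrophages (SSC mid) and granulocytes (SSC high), and then
resolves the ten subpopulations: eosinophils by autofluorescence and
immature granulocytes by low CD11b within granulocytes; the CD14/CD16
monocyte quadrants (blood cM/intM/ncM, milk cMac and the pooled
CD14+/-CD16+ ncMac); and the lymphocyte subsets NK (CD335+), gamma-delta
T (gdTCR+), CD4+ T, CD8+ T and B cells (CD21+) gated sequentially.
Mammary epithelial cells are pan-cytokeratin-positive CD45- milk cells.

Two threshold sources are supported: a *reference* mode with fixed cuts
derived from the configured signature midpoints (the stand-in for
manually placed, FMO-informed gates) and an *auto* mode that places each
cut at the kernel-density valley between the two highest modes of the
parent population, falling back to a configured quantile when the
density is unimodal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, signal, stats

from .config import SCATTER_CHANNELS, StudyConfig
from .events import EventMatrix

DOUBLET_RATIO = 1.5
MIN_AUTO_EVENTS = 500


class GatingError(ValueError):
    pass


# ---------------------------------------------------------------------------
# transforms and thresholds
# ---------------------------------------------------------------------------

def asinh_transform(em: EventMatrix, cofactor: float | dict[str, float]) -> EventMatrix:
    """Channel-wise asinh(value / cofactor); scatter channels untouched.

    ``cofactor`` may be a scalar applied to every non-scatter channel or
    a per-channel mapping.
    """
    data = em.data.copy()
    for ch in data.columns:
        if ch in SCATTER_CHANNELS:
            continue
        cf = cofactor.get(ch) if isinstance(cofactor, dict) else cofactor
        if cf is None:
            continue
        if cf <= 0:
            raise GatingError(f"cofactor for {ch} must be positive, got {cf}")
        data[ch] = np.arcsinh(data[ch] / cf)
    return em.with_data(data)


def _binned_kde(values: np.ndarray, n_grid: int = 512):
    """Silverman-bandwidth Gaussian KDE evaluated on a regular grid via a
    smoothed histogram (exact up to binning; fast for large samples)."""
    sd = float(np.std(values))
    iqr = float(np.subtract(*np.percentile(values, [75, 25])))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    if spread <= 0:
        raise GatingError("constant input: no density structure")
    bw = 1.06 * spread * len(values) ** (-0.2)
    lo, hi = float(values.min()) - 3 * bw, float(values.max()) + 3 * bw
    hist, edges = np.histogram(values, bins=n_grid, range=(lo, hi))
    width = edges[1] - edges[0]
    density = ndimage.gaussian_filter1d(hist.astype(float), sigma=bw / width,
                                        mode="constant")
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, density


def _modes(density: np.ndarray, depth_ratio: float = 0.5) -> np.ndarray:
    """Density modes: local maxima, with adjacent maxima merged into one
    mode unless the valley between them drops below ``depth_ratio`` times
    the lower of the two peaks (suppresses jagged-top artifacts)."""
    peaks, _ = signal.find_peaks(density, height=1e-3 * density.max())
    peaks = list(peaks)
    merged = True
    while merged and len(peaks) > 1:
        merged = False
        for i in range(len(peaks) - 1):
            a, b = peaks[i], peaks[i + 1]
            valley = density[a:b + 1].min()
            if valley > depth_ratio * min(density[a], density[b]):
                peaks.pop(i + 1 if density[b] <= density[a] else i)
                merged = True
                break
    return np.asarray(peaks, dtype=int)


def auto_threshold(values: np.ndarray, fallback_quantile: float = 0.5,
                   n_grid: int = 512) -> float:
    """Density-valley threshold between the two highest modes.

    Deterministic: a kernel density estimate (Silverman bandwidth) is
    scanned for local maxima; the cut is the density minimum between the
    two highest, with ties between equally deep valleys broken toward the
    channel median.  Unimodal input falls back to the given quantile.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < MIN_AUTO_EVENTS:
        raise GatingError(f"need >= {MIN_AUTO_EVENTS} events, got {len(values)}")
    centers, density = _binned_kde(values, n_grid)
    peaks = _modes(density)
    if len(peaks) < 2:
        return float(np.quantile(values, fallback_quantile))
    top2 = peaks[np.argsort(density[peaks])[-2:]]
    left, right = int(top2.min()), int(top2.max())
    segment = density[left:right + 1]
    min_val = segment.min()
    candidates = np.flatnonzero(segment <= min_val * (1 + 1e-12)) + left
    if len(candidates) > 1:
        median = np.median(values)
        candidates = candidates[np.argsort(np.abs(centers[candidates] - median))]
    return float(centers[candidates[0]])


def density_valleys(values: np.ndarray, n_thresholds: int,
                    n_grid: int = 512) -> list[float]:
    """Thresholds separating the ``n_thresholds + 1`` highest density
    modes (e.g. the two SSC cuts splitting lymphocytes / monocytes /
    granulocytes).  Raises if too few modes are present."""
    values = np.asarray(values, dtype=float)
    if len(values) < MIN_AUTO_EVENTS:
        raise GatingError(f"need >= {MIN_AUTO_EVENTS} events, got {len(values)}")
    centers, density = _binned_kde(values, n_grid)
    peaks = _modes(density)
    if len(peaks) < n_thresholds + 1:
        raise GatingError(
            f"found {len(peaks)} density modes, need {n_thresholds + 1}")
    top = np.sort(peaks[np.argsort(density[peaks])[-(n_thresholds + 1):]])
    cuts = []
    for a, b in zip(top[:-1], top[1:]):
        valley = a + int(np.argmin(density[a:b + 1]))
        cuts.append(float(centers[valley]))
    return cuts


# ---------------------------------------------------------------------------
# tree definition
# ---------------------------------------------------------------------------

@dataclass
class GateNode:
    """One decision point of the gating tree.

    ``rule`` is one of threshold-above / threshold-below / quadrant /
    interval; reference thresholds are fixed numbers, auto thresholds are
    recomputed per sample from the parent events.
    """
    name: str
    channels: tuple[str, ...]
    rule: str
    reference: tuple[float, ...]
    fallback_quantile: float = 0.5


@dataclass
class GatingTree:
    """Node collection plus fixed nuisance-gate settings for one matrix.

    Milk and blood trees differ only in the monocyte/macrophage branch
    (three blood monocyte quadrant classes vs. two milk macrophage
    classes) and the milk-only MEC branch.
    """
    matrix: str
    nodes: dict[str, GateNode]
    debris_fsc: float
    debris_ssc: float
    cofactor: float

    def required_channels(self) -> set[str]:
        req = {"FSC-A", "FSC-H", "SSC-A", "Viability"}
        for node in self.nodes.values():
            req.update(node.channels)
        req.discard("panCK")  # tolerated missing (milk early lactation)
        return req


def _midpoint(sigs: dict, pop_a: str, pop_b: str, channel: str) -> float:
    loc = lambda pop: sigs[pop][channel][-1][1]  # last component = dominant/pos
    return 0.5 * (loc(pop_a) + loc(pop_b))


def build_tree(matrix: str, config: StudyConfig | None = None) -> GatingTree:
    """Construct the reference gating tree for a matrix from the
    configured population signatures (threshold = midpoint between the
    negative and positive signature locations)."""
    config = config or StudyConfig()
    sigs = config.signatures()
    if matrix not in ("milk", "blood"):
        raise GatingError(f"unknown matrix {matrix!r}")

    marker_cut = _midpoint(sigs, "cd45neg_other", "cd4_t_cells", "CD45")
    via_cut = 0.5 * (sigs["nk_cells"]["Viability"][0][1]
                     + sigs["dead"]["Viability"][0][1])
    ssc_lo = 0.5 * (sigs["nk_cells"]["SSC-A"][0][1] + sigs["cM" if matrix == "blood" else "cMac"]["SSC-A"][0][1])
    ssc_hi = 0.5 * (sigs["cM" if matrix == "blood" else "cMac"]["SSC-A"][0][1]
                    + sigs["neutrophils"]["SSC-A"][0][1])
    af_cut = 0.5 * (sigs["neutrophils"]["AF"][0][1] + sigs["eosinophils"]["AF"][0][1])
    cd11b_cut = 0.5 * (sigs["immature_granulocytes"]["CD11b"][0][1]
                       + sigs["neutrophils"]["CD11b"][0][1])

    nodes = {
        "dead": GateNode("dead", ("Viability",), "threshold-above", (via_cut,), 0.97),
        "cd45": GateNode("cd45", ("CD45",), "threshold-above", (marker_cut,), 0.05),
        "ssc_split": GateNode("ssc_split", ("SSC-A",), "interval", (ssc_lo, ssc_hi)),
        "eosinophils": GateNode("eosinophils", ("AF",), "threshold-above",
                                (af_cut,), 0.95),
        "immature_granulocytes": GateNode(
            "immature_granulocytes", ("CD11b",), "threshold-below", (cd11b_cut,), 0.05),
        "monocyte_quadrant": GateNode(
            "monocyte_quadrant", ("CD14", "CD16"), "quadrant",
            (marker_cut, marker_cut)),
        "nk_cells": GateNode("nk_cells", ("CD335",), "threshold-above", (marker_cut,), 0.95),
        "gd_t_cells": GateNode("gd_t_cells", ("gdTCR",), "threshold-above",
                               (marker_cut,), 0.8),
        "cd4_t_cells": GateNode("cd4_t_cells", ("CD4",), "threshold-above",
                                (marker_cut,), 0.6),
        "cd8_t_cells": GateNode("cd8_t_cells", ("CD8",), "threshold-above",
                                (marker_cut,), 0.6),
        "b_cells": GateNode("b_cells", ("CD21",), "threshold-above", (marker_cut,), 0.5),
    }
    if matrix == "milk":
        nodes["mec"] = GateNode("mec", ("panCK",), "threshold-above", (marker_cut,), 0.5)

    debris_fsc = 0.5 * (sigs["debris"]["FSC-A"][0][1]
                        + sigs["cd45neg_other"]["FSC-A"][0][1])
    debris_ssc = 0.5 * (sigs["debris"]["SSC-A"][0][1] + sigs["nk_cells"]["SSC-A"][0][1])
    return GatingTree(matrix, nodes, debris_fsc, debris_ssc, config.cofactor)


def _node_thresholds(node: GateNode, parent: EventMatrix, mode: str,
                     ) -> tuple[float, ...]:
    if mode == "reference":
        return node.reference
    cuts = []
    for i, ch in enumerate(node.channels):
        values = parent.data[ch].to_numpy()
        if len(values) < MIN_AUTO_EVENTS:
            cuts.append(node.reference[i])
            continue
        if node.rule == "interval":
            try:
                return tuple(density_valleys(values, 2))
            except GatingError:
                return node.reference
        try:
            cuts.append(auto_threshold(values, node.fallback_quantile))
        except GatingError:
            cuts.append(node.reference[i])
    return tuple(cuts)


def gate_node(parent: EventMatrix, node: GateNode, mode: str = "reference",
              ) -> dict[str, EventMatrix]:
    """Partition a parent population at one node.

    Returns named children: threshold rules give ``{"positive",
    "negative"}`` (for threshold-below, "positive" is the low side);
    interval gives ``{"low", "mid", "high"}``; quadrant gives the four
    ``{"pp", "pn", "np", "nn"}`` subsets keyed by (channel-1, channel-2)
    positivity.  The MEC node returns an empty dict when panCK is absent.
    """
    for ch in node.channels:
        if ch not in parent.data.columns:
            if node.name == "mec":
                return {}
            raise GatingError(f"channel {ch!r} missing for node {node.name}")
    cuts = _node_thresholds(node, parent, mode)
    if node.rule in ("threshold-above", "threshold-below"):
        values = parent.data[node.channels[0]].to_numpy()
        above = values > cuts[0]
        pos = above if node.rule == "threshold-above" else ~above
        return {"positive": parent.subset(pos), "negative": parent.subset(~pos)}
    if node.rule == "interval":
        values = parent.data[node.channels[0]].to_numpy()
        lo, hi = sorted(cuts)
        return {"low": parent.subset(values <= lo),
                "mid": parent.subset((values > lo) & (values <= hi)),
                "high": parent.subset(values > hi)}
    if node.rule == "quadrant":
        a = parent.data[node.channels[0]].to_numpy() > cuts[0]
        b = parent.data[node.channels[1]].to_numpy() > cuts[1]
        return {"pp": parent.subset(a & b), "pn": parent.subset(a & ~b),
                "np": parent.subset(~a & b), "nn": parent.subset(~a & ~b)}
    raise GatingError(f"unknown rule {node.rule!r} at node {node.name}")


# ---------------------------------------------------------------------------
# nuisance exclusion
# ---------------------------------------------------------------------------

def exclude_nuisance(em: EventMatrix, tree: GatingTree, mode: str = "reference",
                     ) -> tuple[EventMatrix, float]:
    """Remove debris, doublets and dead cells; return live singlets and
    viability % (live singlets / non-debris singlets x 100).

    Debris is the joint low-scatter region (fixed reference gate in both
    modes, matching how an acquisition-wide scatter gate is set once);
    doublets exceed the fixed FSC-A/FSC-H ratio; dead cells exceed the
    viability-dye cut.
    """
    if em.n_events == 0:
        raise GatingError(f"sample {em.sample_id}: empty input")
    for ch in ("FSC-A", "FSC-H", "SSC-A", "Viability"):
        if ch not in em.data.columns:
            raise GatingError(f"sample {em.sample_id}: channel {ch!r} missing")
    fsc = em.data["FSC-A"].to_numpy()
    ssc = em.data["SSC-A"].to_numpy()
    debris = (fsc < tree.debris_fsc) & (ssc < tree.debris_ssc)
    cells = em.subset(~debris)
    if cells.n_events == 0:
        raise GatingError(f"sample {em.sample_id}: all events are debris")
    ratio = cells.data["FSC-A"].to_numpy() / np.maximum(
        cells.data["FSC-H"].to_numpy(), 1e-9)
    singlets = cells.subset(ratio <= DOUBLET_RATIO)
    if singlets.n_events == 0:
        raise GatingError(f"sample {em.sample_id}: no singlets left")
    dead_split = gate_node(singlets, tree.nodes["dead"], mode)
    live = dead_split["negative"]
    if live.n_events == 0:
        raise GatingError(f"sample {em.sample_id}: no live events left")
    viability = 100.0 * live.n_events / singlets.n_events
    return live, viability


# ---------------------------------------------------------------------------
# full read-out
# ---------------------------------------------------------------------------

@dataclass
class HRDCCResult:
    """Per-sample percentages of the population hierarchy.

    ``percent_of_parent`` holds each node as a percentage of its direct
    parent (main populations of CD45+, subsets of their main population);
    ``percent_of_cd45`` re-expresses every node as a percentage of all
    CD45+ leukocytes.  ``mec_percent`` (of CD45- events, milk only) is
    None when the panCK channel was not recorded.
    """
    sample_id: str
    matrix: str
    percent_of_parent: dict[str, float]
    percent_of_cd45: dict[str, float]
    viability: float
    mec_percent: float | None = None
    mode: str = "reference"
    denominator: str = "parent"
    counts: dict[str, int] = field(default_factory=dict)

    def to_rows(self) -> list[tuple]:
        rows = [(self.sample_id, node, pct, "parent", self.mode)
                for node, pct in self.percent_of_parent.items()]
        rows += [(self.sample_id, node, pct, "cd45", self.mode)
                 for node, pct in self.percent_of_cd45.items()]
        rows.append((self.sample_id, "viability", self.viability, "parent", self.mode))
        if self.mec_percent is not None:
            rows.append((self.sample_id, "mec", self.mec_percent, "parent", self.mode))
        return rows


_LYMPH_SEQUENCE = ("nk_cells", "gd_t_cells", "cd4_t_cells", "cd8_t_cells", "b_cells")


def run_hrdcc(em: EventMatrix, tree: GatingTree, mode: str = "reference",
              ) -> HRDCCResult:
    """Gate one sample through the full tree.

    The three main populations are reported as percent of CD45+ events
    (summing to 100); subsets as percent of their parent population, with
    percent-of-CD45 equivalents alongside.
    """
    if mode not in ("reference", "auto"):
        raise GatingError(f"unknown mode {mode!r}")
    missing = tree.required_channels() - set(em.data.columns)
    if missing:
        raise GatingError(f"sample {em.sample_id}: missing channels {sorted(missing)}")
    em = asinh_transform(em, tree.cofactor)
    live, viability = exclude_nuisance(em, tree, mode)

    cd45_split = gate_node(live, tree.nodes["cd45"], mode)
    leuk, cd45neg = cd45_split["positive"], cd45_split["negative"]
    if leuk.n_events == 0:
        raise GatingError(f"sample {em.sample_id}: no CD45+ events")

    mec_pct: float | None = None
    if tree.matrix == "milk":
        mec_split = gate_node(cd45neg, tree.nodes["mec"], mode)
        if mec_split and cd45neg.n_events > 0:
            mec_pct = 100.0 * mec_split["positive"].n_events / cd45neg.n_events

    ssc = gate_node(leuk, tree.nodes["ssc_split"], mode)
    lymph, mono, gran = ssc["low"], ssc["mid"], ssc["high"]
    n_leuk = leuk.n_events
    pct_parent: dict[str, float] = {
        "granulocytes": 100.0 * gran.n_events / n_leuk,
        "monocytes_macrophages": 100.0 * mono.n_events / n_leuk,
        "lymphocytes": 100.0 * lymph.n_events / n_leuk,
    }
    counts = {"cd45": n_leuk, "granulocytes": gran.n_events,
              "monocytes_macrophages": mono.n_events, "lymphocytes": lymph.n_events}

    def pct(n: int, denom: int) -> float:
        return 100.0 * n / denom if denom > 0 else 0.0

    # granulocyte branch: eosinophils out first, CD11b-low on the rest
    eos_split = gate_node(gran, tree.nodes["eosinophils"], mode) if gran.n_events \
        else {"positive": gran, "negative": gran}
    eos = eos_split["positive"]
    rest_gran = eos_split["negative"]
    imm_split = gate_node(rest_gran, tree.nodes["immature_granulocytes"], mode) \
        if rest_gran.n_events else {"positive": rest_gran}
    imm = imm_split["positive"]
    pct_parent["eosinophils"] = pct(eos.n_events, gran.n_events)
    pct_parent["immature_granulocytes"] = pct(imm.n_events, gran.n_events)
    counts["eosinophils"] = eos.n_events
    counts["immature_granulocytes"] = imm.n_events

    # monocyte / macrophage quadrants
    if mono.n_events:
        quad = gate_node(mono, tree.nodes["monocyte_quadrant"], mode)
        n_pp, n_pn, n_np = (quad["pp"].n_events, quad["pn"].n_events,
                            quad["np"].n_events)
    else:
        n_pp = n_pn = n_np = 0
    if tree.matrix == "blood":
        pct_parent["cM"] = pct(n_pn, mono.n_events)
        pct_parent["intM"] = pct(n_pp, mono.n_events)
        pct_parent["ncM"] = pct(n_np, mono.n_events)
        counts.update(cM=n_pn, intM=n_pp, ncM=n_np)
    else:
        pct_parent["cMac"] = pct(n_pn, mono.n_events)
        pct_parent["ncMac"] = pct(n_pp + n_np, mono.n_events)  # CD14+/- CD16+
        counts.update(cMac=n_pn, ncMac=n_pp + n_np)

    # lymphocyte branch: sequential exclusion gating
    remaining = lymph
    for name in _LYMPH_SEQUENCE:
        if remaining.n_events:
            split = gate_node(remaining, tree.nodes[name], mode)
            pos, remaining = split["positive"], split["negative"]
            n_pos = pos.n_events
        else:
            n_pos = 0
        pct_parent[name] = pct(n_pos, lymph.n_events)
        counts[name] = n_pos

    parent_of = {"eosinophils": "granulocytes", "immature_granulocytes": "granulocytes",
                 "cM": "monocytes_macrophages", "intM": "monocytes_macrophages",
                 "ncM": "monocytes_macrophages", "cMac": "monocytes_macrophages",
                 "ncMac": "monocytes_macrophages"}
    parent_of.update({name: "lymphocytes" for name in _LYMPH_SEQUENCE})
    pct_cd45 = {k: v for k, v in pct_parent.items()
                if k in ("granulocytes", "monocytes_macrophages", "lymphocytes")}
    for node, parent_name in parent_of.items():
        if node in pct_parent:
            pct_cd45[node] = pct_parent[node] * pct_parent[parent_name] / 100.0

    return HRDCCResult(em.sample_id, tree.matrix, pct_parent, pct_cd45,
                       viability, mec_pct, mode=mode, counts=counts)


def results_frame(results: list[HRDCCResult]) -> pd.DataFrame:
    """Long-format table (sample_id, node, percent, denominator, mode)."""
    rows = []
    for res in results:
        rows.extend(res.to_rows())
    return pd.DataFrame(rows, columns=["sample_id", "node", "percent",
                                       "denominator", "mode"])


def assign_labels(em: EventMatrix, tree: GatingTree, mode: str = "reference",
                  ) -> np.ndarray:
    """Per-event predicted class from the full gating traversal.

    Returns one label per input event: a terminal population name,
    ``mec`` / ``cd45neg_other`` for CD45- events, ``dn_lymphocytes`` for
    marker-negative lymphocytes, or ``debris`` / ``doublet`` / ``dead``
    for excluded events.  Used to score gating against simulator truth.
    """
    n = em.n_events
    em_t = asinh_transform(em, tree.cofactor)
    em_t = em_t.with_data(em_t.data.assign(__index=np.arange(n)))
    labels = np.full(n, "cd45neg_other", dtype=object)

    idx = lambda sub: sub.data["__index"].to_numpy(int)
    fsc = em_t.data["FSC-A"].to_numpy()
    ssc = em_t.data["SSC-A"].to_numpy()
    debris = (fsc < tree.debris_fsc) & (ssc < tree.debris_ssc)
    labels[debris] = "debris"
    cells = em_t.subset(~debris)
    ratio = cells.data["FSC-A"].to_numpy() / np.maximum(
        cells.data["FSC-H"].to_numpy(), 1e-9)
    labels[idx(cells)[ratio > DOUBLET_RATIO]] = "doublet"
    singlets = cells.subset(ratio <= DOUBLET_RATIO)
    dead_split = gate_node(singlets, tree.nodes["dead"], mode)
    labels[idx(dead_split["positive"])] = "dead"
    live = dead_split["negative"]

    cd45_split = gate_node(live, tree.nodes["cd45"], mode)
    leuk, cd45neg = cd45_split["positive"], cd45_split["negative"]
    if tree.matrix == "milk" and cd45neg.n_events:
        mec_split = gate_node(cd45neg, tree.nodes["mec"], mode)
        if mec_split:
            labels[idx(mec_split["positive"])] = "mec"

    ssc_split = gate_node(leuk, tree.nodes["ssc_split"], mode)
    lymph, mono, gran = ssc_split["low"], ssc_split["mid"], ssc_split["high"]

    eos_split = gate_node(gran, tree.nodes["eosinophils"], mode) \
        if gran.n_events else {"positive": gran, "negative": gran}
    labels[idx(eos_split["positive"])] = "eosinophils"
    rest = eos_split["negative"]
    if rest.n_events:
        imm_split = gate_node(rest, tree.nodes["immature_granulocytes"], mode)
        labels[idx(imm_split["positive"])] = "immature_granulocytes"
        labels[idx(imm_split["negative"])] = "neutrophils"

    if mono.n_events:
        quad = gate_node(mono, tree.nodes["monocyte_quadrant"], mode)
        if tree.matrix == "blood":
            labels[idx(quad["pn"])] = "cM"
            labels[idx(quad["pp"])] = "intM"
            labels[idx(quad["np"])] = "ncM"
            labels[idx(quad["nn"])] = "dn_monocytes"
        else:
            labels[idx(quad["pn"])] = "cMac"
            labels[idx(quad["pp"])] = "ncMac"
            labels[idx(quad["np"])] = "ncMac"
            labels[idx(quad["nn"])] = "dn_monocytes"

    remaining = lymph
    for name in _LYMPH_SEQUENCE:
        if not remaining.n_events:
            break
        split = gate_node(remaining, tree.nodes[name], mode)
        labels[idx(split["positive"])] = name
        remaining = split["negative"]
    if remaining.n_events:
        labels[idx(remaining)] = "dn_lymphocytes"
    return labels


# ---------------------------------------------------------------------------
# two-mode concordance
# ---------------------------------------------------------------------------

@dataclass
class GateComparison:
    n_gates: int
    r: float
    slope: float
    intercept: float
    p_value: float


def compare_gating(results_a: list[HRDCCResult], results_b: list[HRDCCResult],
                   ) -> GateComparison:
    """Pool all paired (sample x node) percentages from two result sets
    and regress B on A (simple linear regression), as used to establish
    agreement between manual and automated gating."""
    def pairs(results):
        out = {}
        for res in results:
            for node, v in res.percent_of_parent.items():
                out[(res.sample_id, node)] = v
            out[(res.sample_id, "viability")] = res.viability
            if res.mec_percent is not None:
                out[(res.sample_id, "mec")] = res.mec_percent
        return out

    pa, pb = pairs(results_a), pairs(results_b)
    if set(pa) != set(pb):
        raise GatingError("mismatched sample/node sets between result lists")
    keys = sorted(pa)
    if len(keys) < 3:
        raise GatingError("need at least 3 paired gates")
    x = np.array([pa[k] for k in keys])
    y = np.array([pb[k] for k in keys])
    fit = stats.linregress(x, y)
    return GateComparison(len(keys), float(fit.rvalue), float(fit.slope),
                          float(fit.intercept), float(fit.pvalue))
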
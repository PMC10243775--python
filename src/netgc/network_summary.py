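"""ROI-level percentage summaries of patch-level directed networks.

A detected network is collapsed to either a 4-entry bilateral array --
percentages of significant links in the categories FPC->FPC, FPC->nonFPC,
nonFPC->FPC, nonFPC->nonFPC with hemispheres pooled -- or, for patients,
a 16-entry lateralized array crossing {FPC, nonFPC} x {ipsi, contra} for
source and destination.  Percentages of the total significant link count
are used rather than absolute counts, which makes summaries robust to
per-recording differences in signal quality.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .source_model import RoiMap

logger = logging.getLogger(__name__)

__all__ = [
    "BILATERAL4",
    "LATERALIZED16",
    "ConnectivitySummary",
    "summarize_bilateral",
    "summarize_lateralized",
    "aggregate_group",
    "summary_table",
    "plot_summary_matrix",
]

#: Frozen category order of the bilateral 4-entry summary.
BILATERAL4 = (
    "FPC->FPC", "FPC->nonFPC", "nonFPC->FPC", "nonFPC->nonFPC",
)

#: Frozen category order of the lateralized 16-entry summary: source cell
#: (class, laterality) major, destination cell minor, FPC before nonFPC
#: and ipsi before contra.
_CELLS = [("FPC", "ipsi"), ("FPC", "contra"),
          ("nonFPC", "ipsi"), ("nonFPC", "contra")]
LATERALIZED16 = tuple(
    f"{sc}({sh})->{dc}({dh})"
    for sc, sh in _CELLS for dc, dh in _CELLS
)


@dataclass
class ConnectivitySummary:
    """Percentage of significant links per category for one subject-visit."""

    mode: str                 # "bilateral4" | "lateralized16"
    entries: pd.Series        # indexed by category, sums to 100 (or all 0)
    total_links: int
    subject_id: str = "unknown"
    visit: int = 0
    group: str = "unknown"

    @property
    def degenerate(self) -> bool:
        """True for an empty network, whose percentages are undefined."""
        return self.total_links == 0

    def __post_init__(self):
        expected = BILATERAL4 if self.mode == "bilateral4" else LATERALIZED16
        if tuple(self.entries.index) != expected:
            raise ValueError(f"entries must follow the frozen {self.mode} "
                             "category order")
        if self.total_links > 0:
            assert abs(self.entries.sum() - 100.0) < 1e-9


def _edges_of(network) -> frozenset:
    """Accept a GCNetwork or a bare edge collection."""
    if hasattr(network, "edges"):
        edges = network.edges
    else:
        edges = network
    edges = frozenset((int(s), int(d)) for s, d in edges)
    for s, d in edges:
        if s == d:
            raise ValueError(f"self-link ({s}, {d}) should have been "
                             "excluded upstream")
    return edges


def summarize_bilateral(network, roi_map: RoiMap, **meta) -> ConnectivitySummary:
    """Collapse a network to the 4 bilateral FPC/non-FPC categories.

    Every significant directed link falls in exactly one category from the
    ROI classes of its endpoints.  An empty network yields all-zero
    entries with the degenerate flag set.
    """
    edges = _edges_of(network)
    counts = dict.fromkeys(BILATERAL4, 0)
    for s, d in edges:
        if s >= roi_map.n_patches or d >= roi_map.n_patches:
            raise KeyError(f"patch {max(s, d)} missing from roi_map")
        counts[f"{roi_map.roi_class[s]}->{roi_map.roi_class[d]}"] += 1
    total = len(edges)
    vals = [100.0 * counts[c] / total if total else 0.0 for c in BILATERAL4]
    return ConnectivitySummary(
        mode="bilateral4",
        entries=pd.Series(vals, index=list(BILATERAL4)),
        total_links=total, **meta)


def summarize_lateralized(network, roi_map: RoiMap,
                          **meta) -> ConnectivitySummary:
    """Collapse a patient's network to the 16 lateralized categories.

    Requires a lesion side: categories cross {FPC, nonFPC} x
    {ipsilesional, contralesional} for source and destination.  Each
    direction of a bidirectional pair counts separately.  Controls are
    refused.
    """
    if roi_map.laterality is None:
        raise ValueError("lesion side undefined: lateralized summaries are "
                         "only defined for patients")
    edges = _edges_of(network)
    counts = dict.fromkeys(LATERALIZED16, 0)
    for s, d in edges:
        if s >= roi_map.n_patches or d >= roi_map.n_patches:
            raise KeyError(f"patch {max(s, d)} missing from roi_map")
        sc, sh = roi_map.cell_of(s)
        dc, dh = roi_map.cell_of(d)
        counts[f"{sc}({sh})->{dc}({dh})"] += 1
    total = len(edges)
    vals = [100.0 * counts[c] / total if total else 0.0 for c in LATERALIZED16]
    return ConnectivitySummary(
        mode="lateralized16",
        entries=pd.Series(vals, index=list(LATERALIZED16)),
        total_links=total, **meta)


def aggregate_group(summaries, group_key=None) -> pd.DataFrame:
    """Mean and standard deviation per category across subjects.

    ``summaries`` is an iterable of :class:`ConnectivitySummary` of one
    mode; ``group_key`` optionally maps a summary to a (group, visit)-like
    cell, defaulting to ``(summary.group, summary.visit)``.  Degenerate
    (zero-link) summaries are excluded with a logged count.  Returns a
    table with one row per cell x category and columns mean, sd, n.
    """
    summaries = list(summaries)
    if not summaries:
        raise ValueError("no summaries to aggregate")
    modes = {s.mode for s in summaries}
    if len(modes) > 1:
        raise ValueError(f"cannot aggregate mixed summary modes {modes}")
    if group_key is None:
        group_key = lambda s: (s.group, s.visit)  # noqa: E731
    kept = [s for s in summaries if not s.degenerate]
    n_dropped = len(summaries) - len(kept)
    if n_dropped:
        logger.info("excluded %d degenerate (zero-link) summaries "
                    "from aggregation", n_dropped)
    if not kept:
        raise ValueError("all summaries are degenerate")
    rows = []
    cells: dict = {}
    for s in kept:
        cells.setdefault(group_key(s), []).append(s.entries)
    for cell, entry_list in cells.items():
        stacked = pd.concat(entry_list, axis=1)
        for cat in stacked.index:
            rows.append({
                "cell": cell, "category": cat,
                "mean": float(stacked.loc[cat].mean()),
                "sd": float(stacked.loc[cat].std(ddof=1)) if stacked.shape[1] > 1
                      else 0.0,
                "n": stacked.shape[1],
            })
    return pd.DataFrame(rows)


def summary_table(summaries) -> pd.DataFrame:
    """One row per subject-visit, one column per category (plus metadata).

    This is the input format for the group/visit statistical comparisons.
    """
    rows = []
    for s in summaries:
        row = {"subject": s.subject_id, "group": s.group, "visit": s.visit,
               "total_links": s.total_links, "degenerate": s.degenerate}
        row.update(s.entries.to_dict())
        rows.append(row)
    return pd.DataFrame(rows)


def plot_summary_matrix(summary: ConnectivitySummary, ax=None):
    """Greyscale matrix plot of a summary (cosmetic diagnostic output)."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    side = 2 if summary.mode == "bilateral4" else 4
    mat = summary.entries.to_numpy().reshape(side, side)
    if ax is None:
        _, ax = plt.subplots()
    im = ax.imshow(mat, cmap="Greys", vmin=0,
                   vmax=max(mat.max(), 1e-9))
    labels = ([c.split("->")[0] for c in summary.entries.index[::side]])
    ax.set_xticks(range(side)), ax.set_yticks(range(side))
    ax.set_yticklabels(labels)
    ax.set_xticklabels(labels, rotation=45, ha="right")
    ax.set_xlabel("destination"), ax.set_ylabel("source")
    ax.set_title(f"{summary.subject_id} visit {summary.visit}")
    plt.colorbar(im, ax=ax, label="% of links")
    return ax
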
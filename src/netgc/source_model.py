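"""Cortical patch source spaces, ROI labelling and patch-level dimension
reduction.

The connectivity model works on a coarse icosahedral subdivision of the
cortex: each hemisphere contributes ``10 * 4**level + 2`` patches (84 in
total at level 1, the default working resolution).  Every patch carries a
hemisphere, an anatomical ROI label from the Desikan-Killiany name set and
a number of scalar components (default 4, mimicking a principal-component
reduction of a denser source space).

The frontoparietal cortex (FPC) region of interest is the union of the
``precentral``, ``paracentral`` and ``postcentral`` atlas labels; every
other label is non-FPC.  For patients a lesion hemisphere additionally
splits patches into ipsilesional and contralesional sets.
"""

from __future__ import annotations

import csv
import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "FPC_LABELS",
    "DK_LABELS",
    "Patch",
    "SourceSpace",
    "RoiMap",
    "build_ico_space",
    "assign_rois",
    "load_default_lookup",
    "orient_hemispheres",
    "reduce_patch_components",
]

#: Atlas labels forming the frontoparietal-cortex ROI (motor/premotor strip).
FPC_LABELS = frozenset({"precentral", "paracentral", "postcentral"})

#: The Desikan-Killiany cortical label set (34 labels per hemisphere).
DK_LABELS = (
    "bankssts", "caudalanteriorcingulate", "caudalmiddlefrontal", "cuneus",
    "entorhinal", "frontalpole", "fusiform", "inferiorparietal",
    "inferiortemporal", "insula", "isthmuscingulate", "lateraloccipital",
    "lateralorbitofrontal", "lingual", "medialorbitofrontal",
    "middletemporal", "paracentral", "parahippocampal", "parsopercularis",
    "parsorbitalis", "parstriangularis", "pericalcarine", "postcentral",
    "posteriorcingulate", "precentral", "precuneus",
    "rostralanteriorcingulate", "rostralmiddlefrontal", "superiorfrontal",
    "superiorparietal", "superiortemporal", "supramarginal", "temporalpole",
    "transversetemporal",
)

_SUPPORTED_LEVELS = (0, 1, 2, 3, 4)


@dataclass(frozen=True)
class Patch:
    """A single cortical patch: position in the frozen ordering plus labels."""

    index: int
    hemisphere: str          # "left" | "right"
    roi_label: str | None    # Desikan-Killiany name, None until assigned
    k_components: int = 4


@dataclass(frozen=True)
class SourceSpace:
    """Ordered collection of cortical patches.

    The patch ordering convention is frozen: all left-hemisphere patches
    first (in vertex order), then all right-hemisphere patches.  Edge lists
    and gain matrices refer to this ordering, which makes them portable
    across runs.
    """

    patches: tuple[Patch, ...]
    level: int | None = None

    def __post_init__(self):
        for p in self.patches:
            if p.hemisphere not in ("left", "right"):
                raise ValueError(f"patch {p.index}: bad hemisphere {p.hemisphere!r}")
            if p.k_components < 1:
                raise ValueError(f"patch {p.index}: k_components must be >= 1")

    @property
    def n_patches(self) -> int:
        return len(self.patches)

    @property
    def n_nodes(self) -> int:
        """Total scalar source channels (sum of per-patch component counts)."""
        return sum(p.k_components for p in self.patches)

    @property
    def node_to_patch(self) -> np.ndarray:
        """Map from scalar channel index to patch index."""
        return np.repeat(
            np.arange(self.n_patches),
            [p.k_components for p in self.patches],
        )

    def hemisphere_of(self, patch_index: int) -> str:
        return self.patches[patch_index].hemisphere

    @classmethod
    def from_labels(
        cls,
        roi_labels: list[str],
        hemispheres: list[str] | None = None,
        k_components: int = 1,
    ) -> "SourceSpace":
        """Build a small ad-hoc space directly from label lists.

        Convenient for desk-scale problems where a full icosahedral space
        is unnecessary.  If ``hemispheres`` is omitted, the first half of
        the patches is assigned to the left hemisphere.
        """
        n = len(roi_labels)
        if hemispheres is None:
            hemispheres = ["left"] * (n // 2) + ["right"] * (n - n // 2)
        patches = tuple(
            Patch(i, hemispheres[i], roi_labels[i], k_components)
            for i in range(n)
        )
        return cls(patches=patches, level=None)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "level": self.level,
            "patches": [
                {"index": p.index, "hemisphere": p.hemisphere,
                 "roi_label": p.roi_label, "k_components": p.k_components}
                for p in self.patches
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SourceSpace":
        payload = json.loads(Path(path).read_text())
        patches = tuple(
            Patch(d["index"], d["hemisphere"], d["roi_label"], d["k_components"])
            for d in payload["patches"]
        )
        return cls(patches=patches, level=payload["level"])


@dataclass(frozen=True)
class RoiMap:
    """Per-patch region class (FPC / nonFPC) and optional laterality.

    ``laterality`` maps each patch to ``"ipsi"`` or ``"contra"`` relative to
    a patient's lesion hemisphere; it is ``None`` for control subjects, for
    whom lateralized (16-cell) summaries are refused.
    """

    roi_class: tuple[str, ...]                # "FPC" | "nonFPC" per patch
    laterality: tuple[str, ...] | None = None  # "ipsi" | "contra" per patch

    @property
    def n_patches(self) -> int:
        return len(self.roi_class)

    def cell_of(self, patch_index: int) -> tuple[str, str]:
        """(region class, laterality) of a patch; requires a lesion side."""
        if self.laterality is None:
            raise ValueError("lesion side undefined: lateralized cells are "
                             "only available for patients")
        return self.roi_class[patch_index], self.laterality[patch_index]


def patches_per_hemisphere(level: int) -> int:
    return 10 * 4 ** level + 2


def build_ico_space(level: int, k_components: int = 4) -> SourceSpace:
    """Construct the patch skeleton of an icosahedral source space.

    Each hemisphere gets ``10 * 4**level + 2`` patches (level 1: 42 per
    hemisphere, 84 in total).  ROI labels are unset until
    :func:`assign_rois` is applied.
    """
    if level not in _SUPPORTED_LEVELS:
        raise ValueError(f"unsupported ico level {level}; choose from "
                         f"{_SUPPORTED_LEVELS}")
    per_hemi = patches_per_hemisphere(level)
    patches = []
    for i in range(2 * per_hemi):
        hemi = "left" if i < per_hemi else "right"
        patches.append(Patch(index=i, hemisphere=hemi, roi_label=None,
                             k_components=k_components))
    return SourceSpace(patches=tuple(patches), level=level)


def load_default_lookup() -> dict[int, str]:
    """Load the bundled patch -> Desikan-Killiany label table for ico-1.

    The bundled assignment is a synthetic, fixed convention chosen so that
    every atlas label occurs and the FPC labels cover a realistic share of
    patches.  It is NOT derived from anatomical surfaces; real-data users
    must supply a lookup computed from their own FreeSurfer parcellation.
    """
    ref = resources.files("netgc").joinpath("data/ico1_dk_lookup_synthetic.csv")
    with ref.open() as f:
        reader = csv.DictReader(f)
        return {int(row["patch_index"]): row["roi_label"] for row in reader}


def assign_rois(space: SourceSpace, lookup: dict[int, str]) -> SourceSpace:
    """Label every patch of ``space`` with an atlas ROI from ``lookup``.

    Raises if any patch is missing from the lookup or carries an unknown
    label.  Emits a warning if the resulting FPC/non-FPC partition is
    degenerate (one side empty).
    """
    labelled = []
    for p in space.patches:
        if p.index not in lookup:
            raise KeyError(f"lookup table is missing patch {p.index}")
        label = lookup[p.index]
        if label not in DK_LABELS:
            raise ValueError(f"patch {p.index}: unknown atlas label {label!r}")
        labelled.append(replace(p, roi_label=label))
    out = SourceSpace(patches=tuple(labelled), level=space.level)
    n_fpc = sum(p.roi_label in FPC_LABELS for p in out.patches)
    if n_fpc == 0 or n_fpc == out.n_patches:
        warnings.warn(
            "degenerate FPC/non-FPC partition: "
            f"{n_fpc} of {out.n_patches} patches are FPC", stacklevel=2)
    logger.info("assigned ROIs: %d FPC / %d non-FPC patches",
                n_fpc, out.n_patches - n_fpc)
    return out


def roi_classes(space: SourceSpace) -> tuple[str, ...]:
    for p in space.patches:
        if p.roi_label is None:
            raise ValueError(f"patch {p.index} has no ROI label; run assign_rois")
    return tuple("FPC" if p.roi_label in FPC_LABELS else "nonFPC"
                 for p in space.patches)


def orient_hemispheres(space: SourceSpace,
                       lesion_hemisphere: str | None) -> RoiMap:
    """Build the ROI map, adding ipsi/contra labels for patients.

    ``lesion_hemisphere`` is ``"left"`` or ``"right"`` for patients; passing
    ``None`` (a control subject) yields a map without laterality, and any
    later request for lateralized cells raises ``lesion side undefined``.
    """
    classes = roi_classes(space)
    if lesion_hemisphere is None:
        return RoiMap(roi_class=classes, laterality=None)
    if lesion_hemisphere not in ("left", "right"):
        raise ValueError(f"lesion hemisphere must be left/right/None, got "
                         f"{lesion_hemisphere!r}")
    lat = tuple(
        "ipsi" if p.hemisphere == lesion_hemisphere else "contra"
        for p in space.patches
    )
    return RoiMap(roi_class=classes, laterality=lat)


def reduce_patch_components(patch_gain_columns: np.ndarray, k: int):
    """Orthonormal rank-``k`` basis for one patch's gain block.

    Returns ``(basis, energy_fraction, rank)`` where ``basis`` holds the
    top-``k`` left singular vectors (sensors x k, zero-padded when the
    block rank is below ``k``) and ``energy_fraction`` is the share of
    squared singular values captured by the retained components.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    block = np.atleast_2d(np.asarray(patch_gain_columns, dtype=float))
    if block.shape[1] < 1:
        raise ValueError("patch gain block needs at least one column")
    u, s, _ = np.linalg.svd(block, full_matrices=False)
    tol = s[0] * max(block.shape) * np.finfo(float).eps if s.size else 0.0
    rank = int(np.sum(s > tol))
    keep = min(k, rank)
    basis = np.zeros((block.shape[0], k))
    basis[:, :keep] = u[:, :keep]
    total = float(np.sum(s ** 2))
    energy = float(np.sum(s[:keep] ** 2) / total) if total > 0 else 0.0
    if rank < k:
        logger.info("patch block rank %d < k=%d; basis zero-padded", rank, k)
    return basis, energy, rank
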
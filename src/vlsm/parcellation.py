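"""Atlas parcel coverage of significant voxels and heatmap tables.

Significant voxels are mapped onto one or two label atlases (cortical and
subcortical); for each parcel the *coverage* is the percentage of its
voxels that are significant,

    coverage = 100 * |significant ∩ parcel| / |parcel|,

computed per neurocognitive domain and significance threshold.  Parcels
are ranked by coverage (ties broken by parcel size, then label) and the
top-N reported; a wide parcels-by-domains matrix backs the heatmap
figures.  Voxels carrying no parcel label are kept in a residual row so
the per-parcel counts always conserve the total number of significant
voxels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import GridMismatchError, ValidationError

#: label used for the residual (outside-any-parcel) row
RESIDUAL_LABEL = 0


@dataclass(frozen=True, eq=False)
class ParcelAtlas:
    """Integer-labelled parcellation plus its parcel lookup table.

    ``labels`` is a 3D integer array on the template grid with 0 as
    background; ``parcel_table`` has columns ``label, name, hemisphere,
    parcel_class`` with ``parcel_class`` in {cortical, subcortical}.
    """

    labels: np.ndarray
    parcel_table: pd.DataFrame

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if not np.issubdtype(labels.dtype, np.integer):
            raise ValidationError("atlas labels must be integers")
        present = set(np.unique(labels)) - {RESIDUAL_LABEL}
        table = self.parcel_table
        required = {"label", "name", "hemisphere", "parcel_class"}
        if not required.issubset(table.columns):
            raise ValidationError(f"parcel table needs columns {sorted(required)}")
        known = set(table["label"].astype(int))
        missing = sorted(present - known)
        if missing:
            raise ValidationError(f"labels missing from parcel table: {missing}")
        if table["label"].duplicated().any():
            raise ValidationError("duplicate labels in parcel table")
        object.__setattr__(self, "labels", labels)

    @property
    def parcel_labels(self) -> np.ndarray:
        return np.sort(self.parcel_table["label"].to_numpy(dtype=int))

    def name_of(self, label: int) -> str:
        row = self.parcel_table.loc[self.parcel_table["label"] == label]
        if row.empty:
            raise ValidationError(f"unknown parcel label {label}")
        return str(row["name"].iloc[0])


def coverage(
    sig_mask: np.ndarray,
    atlas: ParcelAtlas,
    domain: str,
    alpha: float,
) -> pd.DataFrame:
    """Per-parcel percentage of voxels that are significant.

    Returns a tidy table with one row per parcel (zero-coverage parcels
    retained) plus a residual row (label 0) collecting significant voxels
    outside every parcel, so that summing ``significant_voxels`` always
    reproduces the mask total.
    """
    sig = np.asarray(sig_mask, dtype=bool)
    if sig.shape != atlas.labels.shape:
        raise GridMismatchError(
            f"significance mask shape {sig.shape} != atlas shape {atlas.labels.shape}"
        )
    n_labels = int(atlas.labels.max()) + 1
    parcel_sizes = np.bincount(atlas.labels.ravel(), minlength=n_labels)
    sig_counts = np.bincount(atlas.labels[sig].ravel(), minlength=n_labels)
    rows = []
    for label in atlas.parcel_labels:
        size = int(parcel_sizes[label])
        hits = int(sig_counts[label])
        rows.append(
            {
                "domain": domain,
                "label": int(label),
                "parcel": atlas.name_of(int(label)),
                "parcel_voxels": size,
                "significant_voxels": hits,
                "coverage_percent": 100.0 * hits / size if size else 0.0,
                "alpha_used": alpha,
            }
        )
    rows.append(
        {
            "domain": domain,
            "label": RESIDUAL_LABEL,
            "parcel": "<unparcellated>",
            "parcel_voxels": int(parcel_sizes[RESIDUAL_LABEL]),
            "significant_voxels": int(sig_counts[RESIDUAL_LABEL]),
            "coverage_percent": 0.0,
            "alpha_used": alpha,
        }
    )
    return pd.DataFrame(rows)


def top_parcels(table: pd.DataFrame, n: int = 15) -> pd.DataFrame:
    """First ``n`` parcels by coverage, excluding the residual row.

    Sort order: coverage descending, then parcel size descending, then
    label ascending — a deterministic total order.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    ranked = (
        table[table["label"] != RESIDUAL_LABEL]
        .sort_values(
            ["coverage_percent", "parcel_voxels", "label"],
            ascending=[False, False, True],
            kind="mergesort",
        )
        .head(n)
        .reset_index(drop=True)
    )
    return ranked


def heatmap_matrix(
    tables: Mapping[str, pd.DataFrame],
    parcel_class: str | None = None,
    atlas: ParcelAtlas | None = None,
    top_n: int | None = 40,
) -> pd.DataFrame:
    """Parcels-by-domains coverage matrix behind the heatmap figures.

    Rows are the union of each domain's ``top_n`` parcels (pass
    ``top_n=None`` to keep all parcels, as done for small subcortical
    atlases), ordered by the maximum coverage across domains; cells hold
    ``coverage_percent`` with 0 for parcels absent from a domain's top
    list.  ``parcel_class`` filters to cortical or subcortical parcels
    when an ``atlas`` is supplied.
    """
    if not tables:
        raise ValidationError("no coverage tables given")
    keep: set[int] | None = None
    if parcel_class is not None:
        if atlas is None:
            raise ValidationError("parcel_class filter requires the atlas")
        keep = set(
            atlas.parcel_table.loc[
                atlas.parcel_table["parcel_class"] == parcel_class, "label"
            ].astype(int)
        )
    ref_labels: set[int] | None = None
    selected: set[int] = set()
    frames = {}
    for domain, table in tables.items():
        sub = table[table["label"] != RESIDUAL_LABEL]
        if keep is not None:
            sub = sub[sub["label"].isin(keep)]
        labels_here = set(sub["label"].astype(int))
        if ref_labels is None:
            ref_labels = labels_here
        elif labels_here != ref_labels:
            raise ValidationError("coverage tables come from inconsistent atlases")
        frames[domain] = sub.set_index("label")
        chosen = sub if top_n is None else top_parcels(sub, top_n)
        selected |= set(chosen["label"].astype(int))
    some = next(iter(frames.values()))
    names = some["parcel"]
    rows = sorted(selected)
    matrix = pd.DataFrame(
        {
            domain: [float(frames[domain].loc[lbl, "coverage_percent"]) for lbl in rows]
            for domain in tables
        },
        index=pd.Index([names.loc[lbl] for lbl in rows], name="parcel"),
    )
    order = matrix.max(axis=1).sort_values(ascending=False, kind="mergesort").index
    return matrix.loc[order]


def save_atlas(atlas: ParcelAtlas, space, labels_path, table_path) -> None:
    """Write the atlas as an integer NIfTI plus a parcel CSV."""
    from .imaging import save_volume

    save_volume(atlas.labels, space, labels_path, dtype=np.int32)
    atlas.parcel_table.to_csv(table_path, index=False)


def load_atlas(labels_path, table_path) -> ParcelAtlas:
    """Read an atlas written by :func:`save_atlas`."""
    import nibabel as nib

    data = np.asarray(nib.load(str(labels_path)).dataobj)
    labels = np.rint(data).astype(np.int32)
    return ParcelAtlas(labels=labels, parcel_table=pd.read_csv(table_path))


def plot_heatmap(matrix: pd.DataFrame, path, title: str = "parcel coverage (%)"):
    """Render a coverage matrix as a PNG heatmap (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(
        figsize=(2 + 0.6 * matrix.shape[1], 1 + 0.25 * matrix.shape[0])
    )
    im = ax.imshow(matrix.to_numpy(), aspect="auto", cmap="hot_r", vmin=0)
    ax.set_xticks(range(matrix.shape[1]), matrix.columns, rotation=45, ha="right")
    ax.set_yticks(range(matrix.shape[0]), matrix.index, fontsize=6)
    ax.set_title(title)
    fig.colorbar(im, ax=ax, label="% of parcel significant")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
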
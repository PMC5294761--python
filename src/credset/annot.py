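"""Chromatin-state segmentations -> binary variant annotations.

Segmentations are BED-style tables (0-based half-open intervals) with a
state label per interval and a cell-type label per track.  From these
we build a binary variant x annotation matrix with one column per
(cell type, state) pair, plus derived "stretch enhancer" columns:
merged runs of active-enhancer (EnhA) state longer than 3 kb, a class
of large regulatory domains enriched for islet regulatory variants.

Variant positions are 1-based (VCF convention); a variant at 1-based
position p overlaps interval [start, end) iff start < p <= end.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "STATE_VOCABULARY",
    "STRETCH_STATE",
    "merge_segments",
    "derive_stretch_enhancers",
    "build_annotation_matrix",
]

STATE_VOCABULARY = frozenset(
    {"TssA", "EnhA", "EnhWk", "Ins", "Tx", "Repr", "TssP", "Quies"}
)
#: label given to merged EnhA runs longer than the stretch threshold
STRETCH_STATE = "StretchEnh"

SEGMENT_COLUMNS = ["chrom", "start", "end", "state", "cell_type"]


def _validate_segments(segments: pd.DataFrame, extra_states: frozenset = frozenset()) -> None:
    missing = [c for c in SEGMENT_COLUMNS if c not in segments.columns]
    if missing:
        raise ValueError(f"segment table missing columns: {missing}")
    if len(segments) and not (segments["start"] < segments["end"]).all():
        raise ValueError("segments must satisfy start < end")
    allowed = STATE_VOCABULARY | extra_states
    unknown = sorted(set(segments["state"]) - allowed)
    if unknown:
        raise ValueError(f"unknown chromatin state label(s): {unknown}")


def merge_segments(segments: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping or book-ended same-state segments.

    Merging is per (cell_type, chrom, state); book-ended records
    (end == next start) count as adjacent, since segmentation tools
    often emit fragmented runs of a single state.  Idempotent.
    """
    _validate_segments(segments, extra_states=frozenset({STRETCH_STATE}))
    if len(segments) == 0:
        return segments.copy()
    out = []
    for (cell, chrom, state), grp in segments.groupby(
        ["cell_type", "chrom", "state"], sort=True
    ):
        grp = grp.sort_values(["start", "end"])
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        cur_s, cur_e = starts[0], ends[0]
        for s, e in zip(starts[1:], ends[1:]):
            if s <= cur_e:  # overlap or book-ended
                cur_e = max(cur_e, e)
            else:
                out.append((chrom, cur_s, cur_e, state, cell))
                cur_s, cur_e = s, e
        out.append((chrom, cur_s, cur_e, state, cell))
    merged = pd.DataFrame(out, columns=SEGMENT_COLUMNS)
    return merged.sort_values(["cell_type", "chrom", "start"]).reset_index(drop=True)


def derive_stretch_enhancers(
    segments: pd.DataFrame, min_length: int = 3000
) -> pd.DataFrame:
    """Active-enhancer runs strictly longer than ``min_length`` bp.

    Adjacent/book-ended EnhA records are merged first, so the call is
    invariant to how the segmentation fragments a run.  The returned
    segments are relabelled :data:`STRETCH_STATE`; the threshold is
    strict (a 3,000 bp run is not a stretch enhancer, a 3,001 bp run is).
    """
    enha = segments[segments["state"] == "EnhA"]
    if len(enha) == 0:
        return pd.DataFrame(columns=SEGMENT_COLUMNS)
    merged = merge_segments(enha)
    stretch = merged[(merged["end"] - merged["start"]) > min_length].copy()
    stretch["state"] = STRETCH_STATE
    return stretch.reset_index(drop=True)


def _overlap_flags(pos: np.ndarray, chrom: np.ndarray, segs: pd.DataFrame) -> np.ndarray:
    """1 where the 1-based position falls inside any segment of ``segs``."""
    flags = np.zeros(len(pos), dtype=np.int8)
    p0 = pos - 1  # 0-based coordinate of the 1-based position
    for c, grp in segs.groupby("chrom"):
        mask = chrom == c
        if not mask.any():
            continue
        grp = grp.sort_values("start")
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        idx = np.searchsorted(starts, p0[mask], side="right") - 1
        ok = idx >= 0
        ok[ok] &= p0[mask][ok] < ends[idx[ok]]
        flags[mask] = ok.astype(np.int8)
    return flags


def build_annotation_matrix(
    variants: pd.DataFrame,
    segments: pd.DataFrame,
    states: tuple[str, ...] = ("EnhA", "EnhWk", "TssA"),
    stretch: str = "additional",
    stretch_min_length: int = 3000,
) -> pd.DataFrame:
    """Binary variant x (cell type, state) membership matrix.

    Parameters
    ----------
    variants : DataFrame
        Needs ``variant_id``, ``chrom`` and 1-based ``pos`` columns.
        Indels are annotated by their anchor position only.
    segments : DataFrame
        0-based half-open intervals with ``state`` and ``cell_type``.
    states : tuple of str
        Which states become annotation columns (one per cell type).
    stretch : {"additional", "replace", "none"}
        Whether stretch-enhancer columns are appended alongside the
        EnhA columns (default), replace them, or are omitted.

    Returns
    -------
    DataFrame
        Indexed by variant_id, one int8 {0,1} column per annotation,
        named ``<cell_type>.<state>``.
    """
    if stretch not in {"additional", "replace", "none"}:
        raise ValueError(f"unknown stretch mode: {stretch!r}")
    unknown = sorted(set(states) - STATE_VOCABULARY)
    if unknown:
        raise ValueError(f"unknown chromatin state label(s): {unknown}")
    _validate_segments(segments)

    pos = variants["pos"].to_numpy(dtype=np.int64)
    chrom = variants["chrom"].to_numpy()
    cell_types = sorted(segments["cell_type"].unique())

    columns: dict[str, np.ndarray] = {}
    keep_enha = not (stretch == "replace")
    for cell in cell_types:
        cell_segs = segments[segments["cell_type"] == cell]
        for state in states:
            if state == "EnhA" and not keep_enha:
                continue
            segs = cell_segs[cell_segs["state"] == state]
            columns[f"{cell}.{state}"] = _overlap_flags(pos, chrom, segs)
    if stretch != "none":
        stretch_segs = derive_stretch_enhancers(segments, stretch_min_length)
        for cell in cell_types:
            segs = stretch_segs[stretch_segs["cell_type"] == cell]
            columns[f"{cell}.{STRETCH_STATE}"] = _overlap_flags(pos, chrom, segs)

    mat = pd.DataFrame(columns, index=pd.Index(variants["variant_id"], name="variant_id"))
    return mat.astype(np.int8)
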
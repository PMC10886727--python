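"""Link-stability filtering and region-of-interest (ROI) connectivity summaries.

Regions follow the motor/frontal layout of a 13-channel 10-20 montage:
three frontal channels (F3, Fz, F4) and three motor channels per hemisphere
(left: C5, CP3, P7; right: C6, CP4, P8).  The midline central/parietal and
occipital channels (Cz, Pz, O1, O2) never enter any summary.

Five contrasts are reported per (subject, session, condition, metric,
window): left and right hemisphere to frontal, between hemispheres, and
within each hemisphere.

A link (channel pair) is *stable* for a given (session, condition, metric,
window) when it is significant (survives the surrogate test) in at least
``within_thr`` of a subject's trials for at least ``across_thr`` of the
subjects.  Unstable links are discarded before averaging.  The ROI summary
for a cell is the mean of the retained links' significant-trial values; a
cell whose retained links were never significant yields a missing value,
not zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .connectivity import ConnectivityTensor
from .surrogates import SignificanceMask

logger = logging.getLogger(__name__)

__all__ = [
    "RoiDefinition",
    "ROIS",
    "CONTRASTS",
    "EXCLUDED_CHANNELS",
    "stability_filter",
    "roi_connectivity",
    "summarise_cells",
]


@dataclass(frozen=True)
class RoiDefinition:
    name: str
    channels: tuple[str, str, str]


ROIS: dict[str, RoiDefinition] = {
    "Frontal": RoiDefinition("Frontal", ("F3", "Fz", "F4")),
    "LHem": RoiDefinition("LHem", ("C5", "CP3", "P7")),
    "RHem": RoiDefinition("RHem", ("C6", "CP4", "P8")),
}

#: contrast name -> (roiA, roiB); A == B means within-ROI
CONTRASTS: dict[str, tuple[str, str]] = {
    "LHem-Frontal": ("LHem", "Frontal"),
    "RHem-Frontal": ("RHem", "Frontal"),
    "LHem-RHem": ("LHem", "RHem"),
    "within-LHem": ("LHem", "LHem"),
    "within-RHem": ("RHem", "RHem"),
}

EXCLUDED_CHANNELS = ("Cz", "Pz", "O1", "O2")


def _roi_pair_indices(
    pairs: Sequence[tuple[str, str]], roi_a: RoiDefinition, roi_b: RoiDefinition
) -> np.ndarray:
    """Indices into ``pairs`` of the between- (9) or within-ROI (3) pairs."""
    if roi_a.name == roi_b.name:
        members = set(roi_a.channels)
        sel = [i for i, (p, q) in enumerate(pairs) if p in members and q in members]
        expected = 3
    else:
        a, b = set(roi_a.channels), set(roi_b.channels)
        sel = [
            i
            for i, (p, q) in enumerate(pairs)
            if (p in a and q in b) or (p in b and q in a)
        ]
        expected = 9
    if len(sel) != expected:
        missing = expected - len(sel)
        raise ValueError(
            f"{missing} ROI channel pair(s) absent from tensor for "
            f"{roi_a.name}-{roi_b.name}"
        )
    return np.asarray(sel)


def stability_filter(
    masks: Mapping[int, np.ndarray],
    within_thr: float = 0.60,
    across_thr: float = 0.50,
) -> np.ndarray:
    """Retain links significant in >= within_thr of trials for >= across_thr of subjects.

    Parameters
    ----------
    masks : mapping subject -> boolean keep array (n_pairs, n_windows, n_trials)
        Significance masks of one (session, condition, metric) cell for every
        subject; trial counts may differ between subjects.

    Returns
    -------
    Boolean array (n_pairs, n_windows): True where the link is retained.
    """
    if not masks:
        raise ValueError("empty mask set")
    per_subject = []
    for subj, keep in masks.items():
        keep = np.asarray(keep, dtype=bool)
        if keep.ndim != 3:
            raise ValueError(f"subject {subj}: mask must be (pairs, windows, trials)")
        per_subject.append(keep.mean(axis=2) >= within_thr)
    stable_frac = np.mean(per_subject, axis=0)
    retained = stable_frac >= across_thr
    logger.info(
        "stability_filter: retained %d/%d (pair, window) links",
        int(retained.sum()), retained.size,
    )
    return retained


def roi_connectivity(
    pruned: ConnectivityTensor,
    retained: np.ndarray,
    roi_a: str,
    roi_b: str,
    keep_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Mean connectivity per window over the retained ROI links of one cell.

    For every window, averages the significant-trial values of the retained
    links among the ROI pair set (9 between-ROI, 3 within-ROI pairs).  When
    ``keep_mask`` is omitted, pruned zeros are excluded by treating exact
    zeros as non-significant.  Returns an array (n_windows,) with NaN where
    no retained link has any significant trial.
    """
    ra, rb = ROIS[roi_a], ROIS[roi_b]
    sel = _roi_pair_indices(pruned.pairs, ra, rb)
    vals = pruned.values[sel]  # (roi_pairs, windows, trials)
    keep = (
        np.asarray(keep_mask, dtype=bool)[sel]
        if keep_mask is not None
        else vals > 0
    )
    ret = np.asarray(retained, dtype=bool)[sel]  # (roi_pairs, windows)
    use = keep & ret[:, :, None]
    num = np.where(use, vals, 0.0).sum(axis=(0, 2))
    cnt = use.sum(axis=(0, 2))
    with np.errstate(invalid="ignore"):
        out = np.where(cnt > 0, num / np.maximum(cnt, 1), np.nan)
    return out


def summarise_cells(
    cells: Mapping[tuple[int, str, str], tuple[ConnectivityTensor, SignificanceMask]],
    within_thr: float = 0.60,
    across_thr: float = 0.50,
    contrasts: Mapping[str, tuple[str, str]] = CONTRASTS,
    pool_conditions: bool = False,
) -> pd.DataFrame:
    """Stability-filter and summarise a whole study into a tidy ROI table.

    ``cells`` maps (subject, session, condition) to the pruned tensor and
    significance mask of one metric.  The stability filter pools subjects
    within each (session, condition); the returned tidy frame has one row per
    (subject, session, condition, metric, window, contrast).

    With ``pool_conditions=True`` the stability filter instead pools each
    subject's trials across the two cue conditions, giving a retained link
    set common to L and R within a session.  Use this when *comparing* the
    conditions: selecting links separately per condition would make the two
    summaries differ through link selection alone.
    """
    if not cells:
        raise ValueError("no cells to summarise")
    by_group: dict[tuple, dict] = {}
    for (subj, session, condition), (tensor, mask) in cells.items():
        gkey = (session,) if pool_conditions else (session, condition)
        by_group.setdefault(gkey, {}).setdefault(subj, {})[condition] = (tensor, mask)

    rows = []
    for gkey, group in sorted(by_group.items()):
        session = gkey[0]
        retained = stability_filter(
            {
                s: np.concatenate([m.keep for _, m in conds.values()], axis=2)
                for s, conds in group.items()
            },
            within_thr,
            across_thr,
        )
        flat = [
            (subj, condition, tensor, mask)
            for subj, conds in group.items()
            for condition, (tensor, mask) in conds.items()
        ]
        for subj, condition, tensor, mask in sorted(flat, key=lambda t: (t[0], t[1])):
            for contrast, (ra, rb) in contrasts.items():
                per_win = roi_connectivity(tensor, retained, ra, rb, keep_mask=mask.keep)
                for w, win in enumerate(tensor.windows):
                    rows.append(
                        {
                            "subject": subj,
                            "session": session,
                            "condition": condition,
                            "metric": tensor.metric,
                            "window": win.label,
                            "contrast": contrast,
                            "value": per_win[w],
                            "retention": "pooled" if pool_conditions else "per-condition",
                        }
                    )
    return pd.DataFrame(rows)
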
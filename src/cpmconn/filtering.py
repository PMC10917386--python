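"""Phenotype-based subject filtering.

Implements the table-expressible exclusion criteria of a multisite
resting-state study: handedness, full-scale IQ, scan length, gross head
motion, mean framewise displacement, presence of the behavioural score,
user-supplied image-QC flags, and a minimum per-site sample size. Criteria
that require the images themselves (signal loss, bad normalization, brain
coverage) are accepted as pre-computed boolean columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class FilterConfig:
    """Thresholds for subject exclusion.

    Any threshold set to ``None`` disables that criterion. ``qc_flag_columns``
    lists boolean phenotype columns where ``True`` marks an image-based QC
    failure (e.g. ``bad_normalization``). Criteria are evaluated in the
    documented order below; the reported reason is the first violated one.
    The site-size criterion runs after all row-level criteria, on the
    surviving subjects.
    """

    qc_flag_columns: list = field(default_factory=list)
    exclude_mixed_handedness: bool = True
    fiq_min: float | None = 70.0
    min_timepoints: int | None = 100
    max_motion_mm: float | None = 2.0
    max_motion_deg: float | None = 2.0
    mfd_max: float | None = 0.2
    require_score: str | None = "score_total"
    min_site_size: int | None = 20


def _row_criteria(cfg: FilterConfig):
    """Ordered (name, required column, predicate-of-row) row-level criteria.

    Predicates return True when the subject violates the criterion. Missing
    values in a thresholded column count as violations (information
    required for inclusion is absent).
    """
    crits = []
    for col in cfg.qc_flag_columns:
        crits.append((f"{col}", col, lambda v: bool(v) if pd.notna(v) else True))
    if cfg.exclude_mixed_handedness:
        crits.append(("handedness mixed/missing", "handedness",
                      lambda v: pd.isna(v) or str(v).lower() in ("mixed", "ambi")))
    if cfg.fiq_min is not None:
        crits.append((f"fiq<{cfg.fiq_min:g}", "fiq",
                      lambda v, t=cfg.fiq_min: pd.isna(v) or v < t))
    if cfg.min_timepoints is not None:
        crits.append((f"timepoints<{cfg.min_timepoints}", "n_timepoints",
                      lambda v, t=cfg.min_timepoints: pd.isna(v) or v < t))
    if cfg.max_motion_mm is not None:
        crits.append((f"motion>{cfg.max_motion_mm:g}mm", "max_motion_mm",
                      lambda v, t=cfg.max_motion_mm: pd.isna(v) or v > t))
    if cfg.max_motion_deg is not None:
        crits.append((f"motion>{cfg.max_motion_deg:g}deg", "max_motion_deg",
                      lambda v, t=cfg.max_motion_deg: pd.isna(v) or v > t))
    if cfg.mfd_max is not None:
        crits.append((f"mfd>{cfg.mfd_max:g}", "mfd",
                      lambda v, t=cfg.mfd_max: pd.isna(v) or v > t))
    if cfg.require_score is not None:
        crits.append((f"missing {cfg.require_score}", cfg.require_score, pd.isna))
    return crits


def filter_subjects(pheno: pd.DataFrame,
                    criteria: FilterConfig | None = None,
                    ) -> tuple[list[str], pd.DataFrame]:
    """Apply exclusion criteria to a phenotype table.

    Parameters
    ----------
    pheno : DataFrame
        Phenotype table with a ``subject_id`` column.
    criteria : FilterConfig
        Active thresholds; defaults mirror a typical multisite study
        (FIQ >= 70, >= 100 timepoints, motion <= 2 mm / 2 deg,
        mFD <= 0.2 mm, site size >= 20).

    Returns
    -------
    included : list of str
        Subject ids passing every active criterion, in table order.
    reasons : DataFrame
        One row per subject: ``subject_id``, ``included`` (bool),
        ``reason`` (first violated criterion, or empty string).

    Notes
    -----
    Filtering is idempotent: the site-size criterion is re-evaluated on the
    filtered table, so filtering an already-filtered table excludes nobody.
    """
    cfg = criteria if criteria is not None else FilterConfig()
    crits = _row_criteria(cfg)
    for name, col, _ in crits:
        if col not in pheno.columns:
            raise ValueError(
                f"filter criterion '{name}' needs missing column '{col}'")
    if cfg.min_site_size is not None and "site" not in pheno.columns:
        raise ValueError("site-size criterion needs missing column 'site'")

    ids = pheno["subject_id"].astype(str).to_numpy()
    reason = np.array([""] * len(pheno), dtype=object)
    for name, col, pred in crits:
        vals = pheno[col]
        hit = vals.map(pred).to_numpy(bool)
        new = hit & (reason == "")
        reason[new] = name

    # site-size criterion on the row-level survivors
    if cfg.min_site_size is not None:
        alive = reason == ""
        counts = pheno.loc[alive, "site"].value_counts()
        small = set(counts[counts < cfg.min_site_size].index)
        small_hit = alive & pheno["site"].isin(small).to_numpy()
        reason[small_hit] = f"site<{cfg.min_site_size}"

    included = [i for i, r in zip(ids, reason) if r == ""]
    report = pd.DataFrame({
        "subject_id": ids,
        "included": reason == "",
        "reason": reason,
    })
    return included, report
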
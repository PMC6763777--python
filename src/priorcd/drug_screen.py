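"""Restrict a raw drug-activity matrix to high/diverse-activity compounds.

A drug is retained when its inter-quartile range (activity diversity) and its
maximum intensity across cell lines both fall in the top quartile of the
respective distributions over all drugs. Drugs with too few measured values
for a stable IQR are excluded before the quartiles are taken.
"""

from __future__ import annotations

import logging

import numpy as np

from .io_formats import DrugActivityMatrix

logger = logging.getLogger(__name__)


def filter_drugs(
    acts: DrugActivityMatrix,
    min_observations: int = 4,
    quantile_method: str = "linear",
) -> DrugActivityMatrix:
    """Keep drugs in the top quartile of both per-drug IQR and per-drug max.

    IQR and max are computed over non-missing samples only. The 75th
    percentile uses inclusive linear interpolation by default
    (``quantile_method`` is passed to numpy); retention compares with >=,
    so an all-identical input retains every drug. Shrinking the matrix and
    re-filtering may shrink it further (the thresholds are re-quartiled).
    """
    if len(acts.drug_ids) == 0:
        raise ValueError("empty drug activity matrix")
    values = acts.values
    n_obs = np.sum(~np.isnan(values), axis=1)
    eligible = n_obs >= min_observations
    n_excluded = int((~eligible).sum())
    if n_excluded:
        logger.info(
            "excluded %d drugs with fewer than %d measured values",
            n_excluded, min_observations,
        )
    if not eligible.any():
        raise ValueError(
            f"no drug has >= {min_observations} measured activity values"
        )
    sub = values[eligible]
    q75 = np.nanpercentile(sub, 75, axis=1)
    q25 = np.nanpercentile(sub, 25, axis=1)
    iqr = q75 - q25
    maxi = np.nanmax(sub, axis=1)

    iqr_thresh = np.quantile(iqr, 0.75, method=quantile_method)
    max_thresh = np.quantile(maxi, 0.75, method=quantile_method)
    keep = (iqr >= iqr_thresh) & (maxi >= max_thresh)
    if not keep.any():
        raise ValueError(
            "no drug passes both filters "
            f"(IQR >= {iqr_thresh:.4g} and max >= {max_thresh:.4g})"
        )
    kept_ids = [d for d, e in zip(acts.drug_ids, eligible) if e]
    kept_ids = [d for d, k in zip(kept_ids, keep) if k]
    logger.info("retained %d of %d drugs", len(kept_ids), len(acts.drug_ids))
    return DrugActivityMatrix(acts.data.loc[kept_ids])
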
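"""Relative quantification of qPCR data by the 2^-ddCt method.

Replicate Ct values are averaged on the Ct scale first; per tissue,
dCt = mean Ct(target) - mean Ct(reference); ddCt is taken against a
calibrator tissue and relative expression is 2^-ddCt (amplification
efficiency fixed at 2).  The calibrator's fold is exactly 1 by construction.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .data_model import CtTable

log = logging.getLogger(__name__)


def delta_delta_ct(
    ct: CtTable,
    target: str,
    reference: str | None = None,
    calibrator: str | None = None,
) -> pd.DataFrame:
    """Relative expression of ``target`` per tissue, 2^-ddCt against ``calibrator``.

    ``reference``/``calibrator`` default to the designations stored on the
    table.  A tissue with target Cts but no reference Cts is reported with
    missing values (and a warning), not a failure; the calibrator tissue must
    have both.  Returns a data frame (tissue, delta_ct, delta_delta_ct, fold).
    """
    reference = reference if reference is not None else ct.reference_gene
    calibrator = calibrator if calibrator is not None else ct.calibrator_tissue
    if reference is None or calibrator is None:
        raise ValueError("a reference gene and a calibrator tissue are required")

    df = ct.records
    mean_ct = df.groupby(["tissue", "gene"])["ct"].mean()

    target_tissues = [t for t in df.loc[df["gene"] == target, "tissue"].drop_duplicates()]
    if not target_tissues:
        raise ValueError(f"no Ct records for target gene {target!r}")
    if calibrator not in target_tissues:
        raise ValueError(f"calibrator tissue {calibrator!r} has no Ct for {target!r}")
    if (calibrator, reference) not in mean_ct.index:
        raise ValueError(f"calibrator tissue {calibrator!r} has no Ct for reference {reference!r}")

    dct = {}
    for tissue in target_tissues:
        if (tissue, reference) in mean_ct.index:
            dct[tissue] = mean_ct[(tissue, target)] - mean_ct[(tissue, reference)]
        else:
            log.warning("tissue %s lacks reference gene %s; reported missing", tissue, reference)
            dct[tissue] = np.nan

    ddct = {t: v - dct[calibrator] for t, v in dct.items()}
    out = pd.DataFrame(
        {
            "tissue": target_tissues,
            "delta_ct": [dct[t] for t in target_tissues],
            "delta_delta_ct": [ddct[t] for t in target_tissues],
        }
    )
    out["fold"] = np.exp2(-out["delta_delta_ct"])
    return out
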
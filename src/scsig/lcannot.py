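"""Latent-component annotation.

Correlates each dimension of the latent space with every signature score
and numeric meta-data column (Spearman, for consistency with the
rank-based autocorrelation machinery) and tests categorical meta-data per
component with a Kruskal-Wallis test.  Useful when the latent space comes
from a factor model and its axes deserve individual interpretation.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.stats

from .autocorr import bh_fdr
from .scoring import SignatureScoreMatrix
from .types import LatentSpace, MetaData

__all__ = ["annotate_components"]


def annotate_components(
    latent: LatentSpace,
    scores: SignatureScoreMatrix | None = None,
    meta: MetaData | None = None,
) -> pd.DataFrame:
    """Spearman correlation of latent dimensions with per-cell features.

    Returns a frame with component, feature, kind (signature / numeric /
    categorical), correlation (NaN for categorical, which uses
    Kruskal-Wallis instead), p_value and fdr (BH within each kind).
    Constant components yield NaN annotations.
    """
    features: list[tuple[str, str, np.ndarray]] = []
    if scores is not None:
        if scores.cell_ids != latent.cell_ids:
            raise ValueError("score cells do not match latent cells")
        for name, row in zip(scores.signature_names, scores.scores):
            features.append((name, "signature", row))
    if meta is not None:
        for col in meta.numeric.columns:
            features.append((col, "numeric", meta.numeric[col].to_numpy(dtype=float)))
        for col in meta.categorical.columns:
            features.append((col, "categorical", meta.categorical[col].to_numpy()))
    if not features:
        raise ValueError("nothing to annotate: provide scores and/or meta-data")

    rows = []
    for d in range(latent.coords.shape[1]):
        comp = latent.coords[:, d]
        constant = np.all(comp == comp[0])
        if constant:
            warnings.warn(f"latent component {d} is constant; annotations are NaN")
        for name, kind, values in features:
            if constant:
                rows.append((d, name, kind, np.nan, np.nan))
                continue
            if kind == "categorical":
                groups = [comp[values == l] for l in pd.unique(values)]
                groups = [g for g in groups if len(g)]
                if len(groups) < 2:
                    rows.append((d, name, kind, np.nan, np.nan))
                    continue
                stat = scipy.stats.kruskal(*groups)
                rows.append((d, name, kind, np.nan, float(stat.pvalue)))
            else:
                if np.all(values == values[0]):
                    rows.append((d, name, kind, np.nan, np.nan))
                    continue
                r = scipy.stats.spearmanr(comp, values)
                rows.append((d, name, kind, float(r.statistic), float(r.pvalue)))
    df = pd.DataFrame(
        rows, columns=["component", "feature", "kind", "correlation", "p_value"]
    )
    df["fdr"] = np.nan
    for kind in df["kind"].unique():
        mask = (df["kind"] == kind).to_numpy()
        df.loc[mask, "fdr"] = bh_fdr(df.loc[mask, "p_value"].to_numpy())
    return df
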
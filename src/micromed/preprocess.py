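"""Normalization and filtering for microbiome, metabolome, and transcriptome matrices.

Conventions implemented here:

* ASV tables are collapsed to the deepest classified taxonomic rank (genus where
  available, otherwise family/order/... with a rank prefix kept in the id).
* Features present in fewer than 20% of samples are dropped (features at exactly
  the threshold are kept).
* Zeros in count compositions are replaced by the 0.5 rounding-error convention
  before renormalizing each sample to relative abundances.
* Continuous omics features are rank-based inverse-normal transformed (Blom
  offset), with a post-transform Shapiro-Wilk screen flagging features for
  removal.
* Expression counts are converted to log2 counts-per-million with the voom-style
  0.5/1 pseudocounts (precision weights are not computed; downstream module and
  correlation analyses consume only the transformed values).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

RANK_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__", "s__")

__all__ = [
    "aggregate_to_genus",
    "prevalence_filter",
    "zero_replace",
    "inverse_normal_transform",
    "logcpm_transform",
    "mad_select",
]


def _deepest_classified(lineage: str) -> str:
    """Return the deepest non-empty rank label of a QIIME-style lineage string.

    ``"p__Firmicutes;c__Clostridia;...;g__Blautia"`` -> ``"g__Blautia"``;
    a lineage classified only to family returns the ``f__`` label.
    """
    if not isinstance(lineage, str) or not lineage.strip():
        raise ValueError("empty lineage string")
    label = None
    for part in lineage.split(";"):
        part = part.strip()
        if len(part) > 3 and part[:3] in RANK_PREFIXES:
            label = part
        elif part and part[:3] not in RANK_PREFIXES:
            # bare label without rank prefix: treat as terminal
            label = part
    if label is None:
        raise ValueError(f"lineage has no classified rank: {lineage!r}")
    return label


def aggregate_to_genus(counts: pd.DataFrame, lineages: pd.Series) -> pd.DataFrame:
    """Collapse an ASV-level count table to its deepest classified taxon labels.

    Parameters
    ----------
    counts : DataFrame, samples x ASVs
    lineages : Series indexed by ASV id, QIIME-style lineage strings.

    ASVs sharing the same deepest classified label are summed.  An ASV
    classified only to family level aggregates under the family id and stays
    distinct from any genus within that family.  Total counts per sample are
    conserved.
    """
    missing = counts.columns.difference(lineages.index)
    if len(missing):
        raise ValueError(f"ASVs without lineage: {list(missing)[:5]}")
    labels = {asv: _deepest_classified(lineages[asv]) for asv in counts.columns}
    out = counts.T.groupby(counts.columns.map(labels)).sum().T
    out.index = counts.index
    return out


def prevalence_filter(table: pd.DataFrame, min_prevalence: float = 0.2) -> pd.DataFrame:
    """Drop features (columns) nonzero in fewer than ``min_prevalence`` of samples.

    The rule is read strictly: a feature nonzero in exactly
    ``min_prevalence * n`` samples is kept.
    """
    if not 0 < min_prevalence <= 1:
        raise ValueError("min_prevalence must be in (0, 1]")
    n = table.shape[0]
    prevalence = (table != 0).sum(axis=0) / n
    keep = prevalence >= min_prevalence
    if not keep.any():
        warnings.warn("prevalence filter removed every feature")
    return table.loc[:, keep]


def zero_replace(counts: pd.DataFrame | np.ndarray, pseudo: float = 0.5):
    """Replace zero counts by ``pseudo`` (maximum rounding error) and close rows to 1.

    Returns a relative-abundance matrix of the same type/labels as the input.
    """
    values = np.asarray(counts, dtype=float)
    if values.ndim != 2:
        raise ValueError("expected a samples x taxa matrix")
    row_tot = values.sum(axis=1)
    if np.any(row_tot == 0):
        ids = (
            list(np.asarray(counts.index)[row_tot == 0])
            if isinstance(counts, pd.DataFrame)
            else list(np.flatnonzero(row_tot == 0))
        )
        raise ValueError(f"all-zero sample rows: {ids}")
    filled = np.where(values == 0, pseudo, values)
    rel = filled / filled.sum(axis=1, keepdims=True)
    if isinstance(counts, pd.DataFrame):
        return pd.DataFrame(rel, index=counts.index, columns=counts.columns)
    return rel


def inverse_normal_transform(values, c: float = 0.375):
    """Rank-based inverse normal transform with Blom offset.

    y_i = Phi^-1((r_i - c) / (n - 2c + 1)) with average ranks for ties.

    Returns ``(transformed, flag)`` where ``flag`` is True when the transformed
    vector fails a Shapiro-Wilk normality test at P < 0.05 (heavily tied or
    otherwise non-normalizable features should be dropped).  A constant vector
    is flagged immediately (ranks undefined).
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or np.sum(np.isfinite(x)) < 3:
        raise ValueError("need >= 3 finite values")
    if np.nanstd(x) == 0:
        return np.zeros_like(x), True
    n = x.size
    ranks = stats.rankdata(x)
    transformed = stats.norm.ppf((ranks - c) / (n - 2 * c + 1))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, p = stats.shapiro(transformed)
    return transformed, bool(p < 0.05)


def logcpm_transform(counts: pd.DataFrame) -> pd.DataFrame:
    """voom-style log2 counts-per-million: log2((count + 0.5) / (libsize + 1) * 1e6)."""
    values = np.asarray(counts, dtype=float)
    if np.any(values < 0):
        raise ValueError("negative counts")
    lib = values.sum(axis=1)
    if np.any(lib == 0):
        raise ValueError("zero library size")
    cpm = np.log2((values + 0.5) / (lib[:, None] + 1.0) * 1e6)
    if isinstance(counts, pd.DataFrame):
        return pd.DataFrame(cpm, index=counts.index, columns=counts.columns)
    return cpm


def mad_select(matrix: pd.DataFrame, k: int) -> pd.DataFrame:
    """Keep the ``k`` features with the largest median absolute deviation.

    MAD is scaled by the 1.4826 consistency constant (does not affect ranking).
    Ties break deterministically toward the lexicographically smaller feature id.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if k > matrix.shape[1]:
        raise ValueError("k exceeds feature count")
    mad = stats.median_abs_deviation(np.asarray(matrix, float), axis=0, scale="normal")
    order = sorted(range(matrix.shape[1]), key=lambda j: (-mad[j], str(matrix.columns[j])))
    keep = sorted(order[:k])
    return matrix.iloc[:, keep]


def drop_report(kept: pd.DataFrame, original: pd.DataFrame, rule: str,
                statistic=None) -> pd.DataFrame:
    """Tidy record of features removed by a filtering rule (for audit TSVs)."""
    dropped = original.columns.difference(kept.columns)
    rep = pd.DataFrame({"feature": list(dropped), "rule": rule})
    if statistic is not None:
        rep["statistic"] = [statistic[f] for f in dropped]
    return rep
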
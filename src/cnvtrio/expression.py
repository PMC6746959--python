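"""Layer 4: carrier vs non-carrier gene expression contrasts in cardiac tissue.

Healthy heart tissue is essentially unobtainable, so the contrast is between
affected probands who carry a region and affected probands of the same
tissue who do not.  FPKM columns are first normalized against housekeeping
genes (default G6PD and ACTB): each sample is rescaled so the geometric mean
of its housekeeping FPKM hits a fixed anchor (default 100), which removes
library-depth scale entirely — multiplying every input FPKM by a constant
leaves the normalized matrix, and hence every downstream p-value and fold
change, bit-identical.

The two-group test is a two-sided Welch t on log2(FPKM + 1); contrasts with
only one or two carriers — common when a region has a single biopsied
carrier — instead report a z score of the carrier mean against the
non-carrier log2 distribution, labelled ``z_outlier`` and never pooled with
Welch results.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy import stats as sps

DEFAULT_HOUSEKEEPING = frozenset({"G6PD", "ACTB"})

#: normalization anchor: housekeeping geometric mean after scaling, in FPKM units
DEFAULT_ANCHOR = 100.0

#: pseudocount for fold changes and log transforms, in normalized FPKM units
EPSILON = 1.0


class ExpressionMatrix:
    """Genes x samples FPKM matrix with tissue labels and a housekeeping set."""

    def __init__(
        self,
        fpkm: pd.DataFrame,
        tissue: dict[str, str],
        housekeeping: frozenset[str] = DEFAULT_HOUSEKEEPING,
    ) -> None:
        if (fpkm.values < 0).any():
            r, c = np.argwhere(fpkm.values < 0)[0]
            raise ValueError(
                f"negative FPKM at gene {fpkm.index[r]!r}, sample {fpkm.columns[c]!r}"
            )
        if fpkm.isna().any().any():
            raise ValueError("missing cells in FPKM matrix")
        missing = set(fpkm.columns) - set(tissue)
        if missing:
            raise ValueError(f"samples without tissue label: {sorted(missing)}")
        self.fpkm = fpkm.astype(float)
        self.tissue = {s: tissue[s] for s in fpkm.columns}
        self.housekeeping = frozenset(housekeeping)

    @property
    def genes(self) -> list[str]:
        return list(self.fpkm.index)

    @property
    def samples(self) -> list[str]:
        return list(self.fpkm.columns)

    def samples_of_tissue(self, tissue: str) -> list[str]:
        return [s for s in self.samples if self.tissue[s] == tissue]


def housekeeping_normalize(
    matrix: ExpressionMatrix,
    target: Union[float, str, None] = None,
) -> ExpressionMatrix:
    """Rescale each sample so its housekeeping geometric mean equals the target.

    ``target`` defaults to the fixed anchor (100 FPKM), making the output
    independent of global input scale; pass ``"cohort"`` to anchor at the
    cohort geometric mean of the housekeeping FPKM instead.  Samples with a
    zero housekeeping value admit no geometric mean and are excluded with a
    warning.  The operation is idempotent.
    """
    hk = sorted(matrix.housekeeping)
    missing = [g for g in hk if g not in matrix.fpkm.index]
    if missing:
        raise ValueError(f"housekeeping genes absent from matrix: {missing}")
    hk_block = matrix.fpkm.loc[hk]
    usable = [s for s in matrix.samples if (hk_block[s] > 0).all()]
    dropped = [s for s in matrix.samples if s not in usable]
    if dropped:
        warnings.warn(
            f"excluding samples with zero housekeeping FPKM: {dropped}"
        )
    if not usable:
        raise ValueError("no sample has strictly positive housekeeping FPKM")
    geo = np.exp(np.log(hk_block[usable]).mean(axis=0))  # per-sample hk geomean
    if target is None:
        ref = DEFAULT_ANCHOR
    elif target == "cohort":
        ref = float(np.exp(np.log(geo).mean()))
    else:
        ref = float(target)
    scaled = matrix.fpkm[usable] * (ref / geo)
    return ExpressionMatrix(scaled, matrix.tissue, matrix.housekeeping)


@dataclass(frozen=True)
class ExpressionContrast:
    gene: str
    tissue: str
    carrier_samples: tuple[str, ...]
    noncarrier_samples: tuple[str, ...]
    mean_fpkm_carrier: float
    mean_fpkm_noncarrier: float
    log2_fold_change: float
    p_value: Optional[float]
    method: str


def compare_expression(
    gene: str,
    tissue: str,
    carriers: list[str],
    matrix: ExpressionMatrix,
) -> ExpressionContrast:
    """Contrast a gene's FPKM between carrier and non-carrier probands.

    Non-carriers are all samples of the tissue not listed as carriers.  With
    >= 3 samples in both groups the p-value is a two-sided Welch t on
    log2(FPKM + 1); with 1-2 carriers it is a two-sided z of the carrier
    mean against the non-carrier log2 distribution (method ``z_outlier``).
    The p-value is absent when fewer than 3 non-carriers are available.
    """
    if gene not in matrix.fpkm.index:
        raise KeyError(f"gene {gene!r} absent from expression matrix")
    tissue_samples = matrix.samples_of_tissue(tissue)
    carrier_set = [s for s in tissue_samples if s in set(carriers)]
    noncarrier = [s for s in tissue_samples if s not in set(carriers)]
    if not noncarrier:
        raise ValueError(f"empty non-carrier group for {gene} in {tissue}")
    if not carrier_set:
        raise ValueError(f"no carrier of {gene} region has tissue {tissue}")

    x_c = matrix.fpkm.loc[gene, carrier_set].to_numpy(dtype=float)
    x_n = matrix.fpkm.loc[gene, noncarrier].to_numpy(dtype=float)
    mean_c, mean_n = float(x_c.mean()), float(x_n.mean())
    lfc = float(np.log2((mean_c + EPSILON) / (mean_n + EPSILON)))
    log_c, log_n = np.log2(x_c + EPSILON), np.log2(x_n + EPSILON)

    p: Optional[float]
    if len(noncarrier) < 3:
        p, method = None, "insufficient_noncarriers"
    elif len(carrier_set) >= 3:
        p = float(sps.ttest_ind(log_c, log_n, equal_var=False).pvalue)
        method = "welch_t"
    else:
        s_n = float(log_n.std(ddof=1))
        if s_n == 0.0:
            p, method = None, "z_outlier_degenerate"
        else:
            z = (float(log_c.mean()) - float(log_n.mean())) / (
                s_n / np.sqrt(len(carrier_set))
            )
            p = float(2.0 * sps.norm.sf(abs(z)))
            method = "z_outlier"
    return ExpressionContrast(
        gene,
        tissue,
        tuple(carrier_set),
        tuple(noncarrier),
        mean_c,
        mean_n,
        lfc,
        p,
        method,
    )


def contrast_table(contrasts: list[ExpressionContrast]) -> pd.DataFrame:
    """Tabular view of contrasts (gene, tissue, group sizes, means, log2FC, p)."""
    return pd.DataFrame(
        {
            "gene": [c.gene for c in contrasts],
            "tissue": [c.tissue for c in contrasts],
            "n_carrier": [len(c.carrier_samples) for c in contrasts],
            "n_noncarrier": [len(c.noncarrier_samples) for c in contrasts],
            "mean_fpkm_carrier": [c.mean_fpkm_carrier for c in contrasts],
            "mean_fpkm_noncarrier": [c.mean_fpkm_noncarrier for c in contrasts],
            "log2_fold_change": [c.log2_fold_change for c in contrasts],
            "p_value": [c.p_value for c in contrasts],
            "method": [c.method for c in contrasts],
        }
    )
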
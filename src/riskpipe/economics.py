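"""Economic concentration indices and the municipality risk matrix.

For a product i (here: pine) in municipality j, with VP_ij the product's
value in j, VP_j the municipality's total forestry value, and national
totals VP_iBR, VP_BR:

    LQ_ij  = (VP_ij / VP_j) / (VP_iBR / VP_BR)     specialization
    HHI_ij = VP_ij / VP_iBR − VP_j / VP_BR         concentration (sums to 0)
    RP_ij  = VP_ij / VP_iBR                        national share (sums to 1)

The normalized Concentration Index nCI_ij = θ1·LQ + θ2·RP + θ3·HHI
combines the z-standardized indices with non-negative weights θ derived
from a PCA of their correlation matrix (explained-variance-weighted
absolute loadings, renormalized to sum 1).

Economic risk crosses five Jenks classes of municipality mean
suitability with five Jenks classes of nCI; the two class indices are
averaged and mapped to four levels: very low (0–1.5], low (1.5–2.0],
moderate (2.0–3.0], high (3.0–5.0].
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .riskmap import jenks_breaks

__all__ = [
    "validate_production_table",
    "compute_lq",
    "compute_hhi",
    "compute_rp",
    "compute_weights",
    "compute_nci",
    "economic_indices",
    "classify_economic_risk",
    "RISK_LEVELS",
]

RISK_LEVELS = ("very low", "low", "moderate", "high")
_RISK_UPPER_BOUNDS = (1.5, 2.0, 3.0, 5.0)  # right-closed intervals
INDEX_ORDER = ("LQ", "RP", "HHI")  # θ1, θ2, θ3


def validate_production_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the muni_id / vp_product / vp_forestry_total contract."""
    required = {"muni_id", "vp_product", "vp_forestry_total"}
    if not required.issubset(table.columns):
        raise ValueError(f"production table must have columns {sorted(required)}")
    if table["muni_id"].duplicated().any():
        raise ValueError("duplicate muni_id in production table")
    if (table["vp_product"] < 0).any():
        raise ValueError("negative product value")
    if (table["vp_product"] > table["vp_forestry_total"] + 1e-9).any():
        raise ValueError("vp_product exceeds vp_forestry_total for some rows")
    if table["vp_product"].sum() <= 0 or table["vp_forestry_total"].sum() <= 0:
        raise ValueError("national totals must be positive")
    return table


def compute_lq(table: pd.DataFrame) -> pd.Series:
    """Location quotient; zero-production municipalities get LQ = 0."""
    validate_production_table(table)
    vp_i_br = table["vp_product"].sum()
    vp_br = table["vp_forestry_total"].sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        local_share = table["vp_product"] / table["vp_forestry_total"]
    lq = local_share / (vp_i_br / vp_br)
    lq = lq.where(table["vp_forestry_total"] > 0, 0.0)
    return lq.rename("LQ")


def compute_hhi(table: pd.DataFrame) -> pd.Series:
    """Modified Hirschman–Herfindahl index; sums to zero over municipalities."""
    validate_production_table(table)
    return (
        table["vp_product"] / table["vp_product"].sum()
        - table["vp_forestry_total"] / table["vp_forestry_total"].sum()
    ).rename("HHI")


def compute_rp(table: pd.DataFrame) -> pd.Series:
    """Relative participation (share of national product value)."""
    validate_production_table(table)
    return (table["vp_product"] / table["vp_product"].sum()).rename("RP")


def _standardize(col: np.ndarray) -> np.ndarray:
    return (col - col.mean()) / col.std()


def compute_weights(indices: pd.DataFrame) -> np.ndarray:
    """PCA-derived weights θ over the (LQ, RP, HHI) columns.

    Eigen-decomposition of the 3×3 correlation matrix; each index's
    weight is the sum over components of (explained-variance share) ×
    (normalized absolute loading), renormalized so Σθ = 1.  Absolute
    loadings remove the eigenvector sign ambiguity.
    """
    if len(indices) < 4:
        raise ValueError("need at least 4 municipalities for PCA weights")
    for name in INDEX_ORDER:
        if indices[name].std() == 0:
            raise ValueError(f"index column {name} is constant")
    x = np.column_stack([_standardize(indices[n].to_numpy(float))
                         for n in INDEX_ORDER])
    corr = np.corrcoef(x, rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(corr)
    eigvals = np.clip(eigvals, 0.0, None)
    var_share = eigvals / eigvals.sum()
    abs_load = np.abs(eigvecs)
    abs_load = abs_load / abs_load.sum(axis=0, keepdims=True)
    theta = abs_load @ var_share
    return theta / theta.sum()


def compute_nci(indices: pd.DataFrame, theta: np.ndarray) -> pd.Series:
    """Weighted sum of the z-standardized index columns (θ1·LQ + θ2·RP + θ3·HHI)."""
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (3,):
        raise ValueError("theta must have three components")
    z = np.column_stack([_standardize(indices[n].to_numpy(float))
                         for n in INDEX_ORDER])
    return pd.Series(z @ theta, index=indices.index, name="nCI")


def economic_indices(table: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """All four indices per municipality plus the PCA weights θ."""
    out = pd.DataFrame({"muni_id": table["muni_id"]})
    out["LQ"] = compute_lq(table)
    out["HHI"] = compute_hhi(table)
    out["RP"] = compute_rp(table)
    theta = compute_weights(out)
    out["nCI"] = compute_nci(out, theta)
    return out, theta


def _risk_level(mean_score: float) -> str:
    for level, upper in zip(RISK_LEVELS, _RISK_UPPER_BOUNDS):
        if mean_score <= upper:
            return level
    return RISK_LEVELS[-1]


def _jenks_class(values: pd.Series, k: int = 5) -> pd.Series:
    breaks = jenks_breaks(values.to_numpy(float), k)
    cls = np.searchsorted(breaks, values.to_numpy(float), side="left") + 1
    return pd.Series(np.clip(cls, 1, k), index=values.index)


def classify_economic_risk(
    mean_suitability: pd.Series, nci: pd.Series, k: int = 5
) -> pd.DataFrame:
    """Two-dimensional risk matrix over municipalities.

    Both inputs (indexed by muni_id) are classified into five Jenks
    classes (1 = lowest, 5 = highest); the per-municipality mean of the
    two class indices sets the risk level via the four right-closed
    intervals listed in the module docstring.
    """
    missing = set(mean_suitability.index) ^ set(nci.index)
    if missing:
        raise ValueError(
            f"municipality sets differ between inputs: {sorted(missing)}"
        )
    nci = nci.reindex(mean_suitability.index)
    occ_class = _jenks_class(mean_suitability, k)
    nci_class = _jenks_class(nci, k)
    mean_score = (occ_class + nci_class) / 2.0
    return pd.DataFrame(
        {
            "muni_id": mean_suitability.index,
            "occ_class": occ_class.to_numpy(),
            "nci_class": nci_class.to_numpy(),
            "mean_score": mean_score.to_numpy(),
            "risk_level": [_risk_level(s) for s in mean_score],
        }
    ).set_index("muni_id")
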
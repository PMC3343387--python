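"""Statistics over per-fragment pair interaction energies (PIE).

Works on a fragments x ligands matrix of PIE totals, optionally decomposed
into PIEDA terms (electrostatic ES, exchange-repulsion EX, charge transfer
plus mixed CTmix, dispersion DI) and annotated with per-ligand pIC50.

Conventions:

* Fragment labels follow the FMO convention: fragment *i* contains the
  backbone carbonyl of residue *i - 1* (so e.g. a ``Thr201`` fragment carries
  the Lys200 backbone carbonyl).  Labels here are fragment labels — keep the
  shift in mind before attributing an interaction to a residue's own
  backbone.
* Variance and covariance use the population normalization (denominator n):
  the ligand panel is the entire set under study, and the statistics are
  descriptive, not inferential.  Sample normalization would scale every
  value by n/(n-1) and leave all rankings unchanged.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("solvsite")

PIEDA_TERMS = ["ES", "EX", "CTmix", "DI"]


@dataclass
class PIEMatrix:
    """Complete fragments x ligands PIE table (kcal/mol).

    ``pieda`` maps term name to a DataFrame aligned with ``total``;
    ``pic50`` is a per-ligand Series; ``decimals`` records the printed
    decimal places of each cell (for rounding-aware validation) when the
    matrix was read from a file.
    """

    fragments: list[str]
    ligands: list[str]
    total: pd.DataFrame
    pieda: dict[str, pd.DataFrame] | None = None
    pic50: pd.Series | None = None
    decimals: dict[str, pd.DataFrame] | None = None

    def __post_init__(self):
        if self.total.shape != (len(self.fragments), len(self.ligands)):
            raise ValueError("total matrix shape mismatch")
        if self.total.isna().any().any():
            raise ValueError("PIE matrix is incomplete")
        if self.pieda is not None:
            present = [t for t in PIEDA_TERMS if t in self.pieda]
            if len(present) != len(PIEDA_TERMS):
                raise ValueError(
                    f"PIEDA terms must be all present or all absent; "
                    f"found {present}")

    @property
    def n_ligands(self) -> int:
        return len(self.ligands)


@dataclass(frozen=True)
class ResidueStat:
    fragment: str
    variance: float
    covariance_with_pic50: float | None
    rank_by_variance: int
    rank_by_abs_covariance: int | None

    def __post_init__(self):
        if self.variance < -1e-12:
            raise ValueError("variance must be non-negative")


def delta_pie(m: PIEMatrix, reference: str) -> pd.DataFrame:
    """PIE differences against a reference ligand; the reference column is 0."""
    if reference not in m.ligands:
        raise KeyError(f"reference ligand {reference!r} not in table "
                       f"(have {m.ligands})")
    return m.total.sub(m.total[reference], axis=0)


def residue_variance(m: PIEMatrix) -> pd.Series:
    """Population variance of PIE across the ligand panel, per fragment."""
    if m.n_ligands < 2:
        raise ValueError("variance needs at least 2 ligands")
    return m.total.var(axis=1, ddof=0)


def residue_potency_covariance(m: PIEMatrix) -> pd.Series:
    """Population covariance of PIE with pIC50, per fragment.

    Covariance (rather than correlation) keeps the magnitude of the PIE
    variation: fragments whose interaction energy both varies strongly and
    tracks potency stand out, while correlation alone would also flag
    fragments with tiny but consistent variation.
    """
    if m.pic50 is None:
        raise ValueError("PIE matrix carries no pIC50 values")
    if m.n_ligands < 2:
        raise ValueError("covariance needs at least 2 ligands")
    p = m.pic50.reindex(m.ligands).to_numpy(dtype=float)
    vals = m.total.to_numpy(dtype=float)
    cov = ((vals - vals.mean(axis=1, keepdims=True))
           * (p - p.mean())).mean(axis=1)
    return pd.Series(cov, index=m.total.index)


def validate_pieda(m: PIEMatrix, default_tolerance: float = 1e-9
                   ) -> pd.DataFrame:
    """Check total = ES + EX + CTmix + DI per cell, rounding-aware.

    When printed decimal places are known (table read from file), the
    tolerance for a cell is the accumulated half-unit-in-the-last-place of
    its four components plus the total's; otherwise ``default_tolerance``.
    Returns a long DataFrame with residual and pass/fail per cell.
    """
    if m.pieda is None:
        raise ValueError("PIE matrix carries no PIEDA terms")
    recomposed = sum(m.pieda[t] for t in PIEDA_TERMS)
    residual = m.total - recomposed
    if m.decimals is not None:
        tol = sum(0.5 * 10.0 ** (-m.decimals[c].astype(float))
                  for c in ["total", *PIEDA_TERMS])
    else:
        tol = m.total * 0 + default_tolerance
    rows = []
    for f in m.fragments:
        for lig in m.ligands:
            r = float(residual.loc[f, lig])
            t = float(tol.loc[f, lig])
            rows.append({"fragment": f, "ligand": lig, "residual": r,
                         "tolerance": t, "passed": abs(r) <= t})
    out = pd.DataFrame(rows)
    n_fail = int((~out["passed"]).sum())
    logger.info("validate_pieda: %d/%d cells pass", len(out) - n_fail, len(out))
    return out


def rank_residues(m: PIEMatrix, k: int) -> list[ResidueStat]:
    """Top-k fragments by PIE variance and by |covariance with pIC50|.

    Returns one :class:`ResidueStat` per fragment with rank fields (1-based;
    ties broken by fragment label order as listed in the table).  The
    returned list is sorted by variance rank and truncated to ``k``; when the
    table has no pIC50 the covariance fields are None.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(m.fragments):
        warnings.warn(f"k={k} exceeds fragment count {len(m.fragments)}; "
                      f"truncating", stacklevel=2)
        k = len(m.fragments)
    var = residue_variance(m)
    cov = residue_potency_covariance(m) if m.pic50 is not None else None
    order = list(m.fragments)
    by_var = sorted(order, key=lambda f: (-var[f], order.index(f)))
    var_rank = {f: i + 1 for i, f in enumerate(by_var)}
    if cov is not None:
        by_cov = sorted(order, key=lambda f: (-abs(cov[f]), order.index(f)))
        cov_rank = {f: i + 1 for i, f in enumerate(by_cov)}
    stats = []
    for f in by_var[:k]:
        stats.append(ResidueStat(
            fragment=f,
            variance=float(var[f]),
            covariance_with_pic50=None if cov is None else float(cov[f]),
            rank_by_variance=var_rank[f],
            rank_by_abs_covariance=None if cov is None else cov_rank[f]))
    return stats
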
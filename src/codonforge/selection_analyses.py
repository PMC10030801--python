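"""Mutation-versus-selection diagnostics.

Four classical diagnostics over the per-gene statistics of one species:

* neutrality plot — OLS regression of GC12 on GC3 across genes; a slope
  near 1 indicates directional mutation pressure acting on all codon
  positions, a slope near 0 indicates selection constraining positions 1-2;
* ENC-vs-GC3s plot — Wright's expected curve
  ENC_exp(s) = 2 + s + 29 / (s^2 + (1-s)^2) and the signed ENC ratio
  (ENC_exp - ENC_obs) / ENC_exp, positive when observed bias exceeds what
  third-position composition alone explains;
* PR2 bias — the per-gene point (G3/(G3+C3), A3/(A3+T3)) at third positions
  of four-fold degenerate families; (0.5, 0.5) means no strand asymmetry;
* pairwise Pearson correlations between usage indices across genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .codon_statistics import CodonCountTable, CompositionProfile
from .expression_indices import UsageIndexRecord
from .genetic_code import GeneticCode, STANDARD_CODE


@dataclass(frozen=True)
class NeutralityFit:
    points: tuple[tuple[float, float], ...]  # (GC3, GC12) as fractions
    slope: float
    intercept: float
    r_squared: float
    pearson_r: float
    p_value: float


@dataclass(frozen=True)
class ENCPlotRecord:
    gene: str
    gc3s: float
    enc_obs: float
    enc_exp: float

    @property
    def enc_ratio(self) -> float:
        return enc_ratio(self.enc_obs, self.enc_exp)


@dataclass(frozen=True)
class PR2Record:
    gene: str
    x: float | None  # G3/(G3+C3); None when the axis has no counts
    y: float | None  # A3/(A3+T3)

    @property
    def ok(self) -> bool:
        return self.x is not None and self.y is not None


def neutrality_fit(gene_profiles: list[CompositionProfile]) -> NeutralityFit:
    """OLS of GC12 on GC3 over genes, with Pearson r and its t-test p-value."""
    if len(gene_profiles) < 3:
        raise ValueError("neutrality fit needs at least 3 genes")
    gc3 = np.array([p.GC3 for p in gene_profiles]) / 100.0
    gc12 = np.array([p.GC12 for p in gene_profiles]) / 100.0
    if np.allclose(gc3, gc3[0]):
        raise ValueError("zero variance in GC3: slope undefined")
    res = stats.linregress(gc3, gc12)
    return NeutralityFit(
        points=tuple(zip(gc3.tolist(), gc12.tolist())),
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        pearson_r=float(res.rvalue),
        p_value=float(res.pvalue),
    )


def enc_expected(gc3s: float) -> float:
    """Wright's expected ENC under mutation pressure alone at GC3s = s."""
    if not 0.0 <= gc3s <= 1.0:
        raise ValueError(f"GC3s must be in [0, 1], got {gc3s}")
    s = gc3s
    return 2.0 + s + 29.0 / (s * s + (1.0 - s) ** 2)


def enc_ratio(enc_obs: float, enc_exp: float) -> float:
    """Signed relative deviation (ENC_exp - ENC_obs) / ENC_exp."""
    if enc_exp <= 0:
        raise ValueError("ENC_exp must be positive")
    return (enc_exp - enc_obs) / enc_exp


def pr2_point(
    cct: CodonCountTable,
    code: GeneticCode = STANDARD_CODE,
    gene: str = "",
    scope: str = "fourfold",
) -> PR2Record:
    """Third-position PR2 coordinates x = G3/(G3+C3), y = A3/(A3+T3).

    ``scope='fourfold'`` (default, Sueoka's convention) restricts the tally
    to four-fold degenerate families, where the third base is free of
    amino-acid constraint; ``scope='all-synonymous'`` uses every
    multi-codon-family codon. An axis with zero counts is flagged None.
    """
    if scope not in ("fourfold", "all-synonymous"):
        raise ValueError(f"unknown PR2 scope: {scope}")
    tally = {b: 0 for b in "ACGT"}
    for codon, n in cct.counts.items():
        fam = code.family_of(codon)
        if scope == "fourfold" and len(fam) != 4:
            continue
        if scope == "all-synonymous" and len(fam) < 2:
            continue
        tally[codon[2]] += n
    gc = tally["G"] + tally["C"]
    at = tally["A"] + tally["T"]
    return PR2Record(
        gene=gene,
        x=tally["G"] / gc if gc > 0 else None,
        y=tally["A"] / at if at > 0 else None,
    )


def index_correlations(
    records: list[UsageIndexRecord], indicators: list[str]
) -> pd.DataFrame:
    """Pairwise Pearson correlations of usage indices across genes.

    Returns a long-format frame (i, j, r, p, p_holm, stars) with Holm-
    adjusted p-values alongside the raw ones; constant indicators yield
    NaN r with a flag rather than an error.
    """
    if len(records) < 3:
        raise ValueError("correlation analysis needs at least 3 genes")
    data = {
        ind: np.array([np.nan if r[ind] is None else float(r[ind]) for r in records])
        for ind in indicators
    }
    for ind, v in data.items():
        if np.isnan(v).all():
            raise ValueError(f"indicator {ind!r} missing from all records")
    rows = []
    for a_i, a in enumerate(indicators):
        for b in indicators[a_i + 1 :]:
            x, y = data[a], data[b]
            mask = ~(np.isnan(x) | np.isnan(y))
            if mask.sum() < 3 or np.allclose(x[mask], x[mask][0]) or np.allclose(y[mask], y[mask][0]):
                rows.append((a, b, np.nan, np.nan, True))
                continue
            r, p = stats.pearsonr(x[mask], y[mask])
            rows.append((a, b, float(r), float(p), False))
    df = pd.DataFrame(rows, columns=["i", "j", "r", "p", "constant"])
    valid = df["p"].notna()
    df["p_holm"] = np.nan
    if valid.any():
        df.loc[valid, "p_holm"] = multipletests(df.loc[valid, "p"], method="holm")[1]
    df["stars"] = df["p"].map(
        lambda p: "**" if p < 0.01 else ("*" if p < 0.05 else "")
    )
    return df
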
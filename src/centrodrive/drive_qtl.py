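"""Quantifying female meiotic drive from selfed-progeny counts and scanning
for unlinked modifier loci.

The drive phenotype of an F2 plant is the probability f that its female
meiosis transmits the driving allele (%D_fem).  Under Mendelian male
transmission (m = 0.5), the frequency of the driving allele among selfed F3
progeny is p = (f + m)/2, so the method-of-moments estimator from genotype
counts is f_hat = 2*p_hat - m, clipped to [0, 1].

The modifier scan is a Haley-Knott-style regression of %D_fem on the
expected allele dosage computed from marker genotype probabilities, with the
drive-locus (MDL11) genotype as a binary cofactor in both nested models, so
the LOD score measures each marker's effect beyond the drive locus itself:
LOD = (n/2) * log10(RSS_null / RSS_full).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GENO_CLASSES = ("GG", "NG", "NN")  # column order of probability triples
MDL11_CLASSES = ("DD_MINUS", "Dd")


@dataclass
class F2Panel:
    """An F2 cohort: drive-locus class, marker probabilities, and F3 counts.

    ``probs`` has shape (n_f2, n_markers, 3) over :data:`GENO_CLASSES`;
    ``f3_counts`` has shape (n_f2, 3) ordered (n_DD, n_Dhet, n_other).
    """

    f2_ids: list[str]
    mdl11: np.ndarray                 # per-F2 class label
    markers: pd.DataFrame             # marker, chrom, cM
    probs: np.ndarray
    f3_counts: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n, m = len(self.f2_ids), len(self.markers)
        self.probs = np.asarray(self.probs, dtype=float)
        self.f3_counts = np.asarray(self.f3_counts, dtype=int)
        if self.probs.shape != (n, m, 3):
            raise ValueError("probs must be (n_f2, n_markers, 3)")
        if self.f3_counts.shape != (n, 3):
            raise ValueError("f3_counts must be (n_f2, 3)")
        if (self.f3_counts < 0).any():
            raise ValueError("negative F3 counts")
        sums = self.probs.sum(axis=2)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("genotype probabilities must sum to 1")
        bad = set(self.mdl11) - set(MDL11_CLASSES)
        if bad:
            raise ValueError(f"unknown MDL11 classes: {sorted(bad)}")

    @property
    def n_f3(self) -> np.ndarray:
        return self.f3_counts.sum(axis=1)

    def pct_d_fem(self, male_transmission: float = 0.5) -> np.ndarray:
        return np.array(
            [
                np.nan if (v := estimate_drive_strength(c, male_transmission)) is None else v
                for c in self.f3_counts
            ]
        )


@dataclass
class LodProfile:
    markers: pd.DataFrame
    lod: np.ndarray
    smoothed: np.ndarray
    cofactor: bool
    n_used: int
    flags: list[str] = field(default_factory=list)


def estimate_drive_strength(f3_counts, male_transmission: float = 0.5) -> float | None:
    """%D_fem from selfed-F3 genotype counts (n_DD, n_Dhet, n_other).

    p_hat = (2 n_DD + n_Dhet) / (2 n_total) estimates the driving-allele
    frequency among progeny; inverting p = (f + m)/2 gives
    f_hat = 2 p_hat - m, clipped to [0, 1].  None when no progeny.
    """
    n_dd, n_het, n_other = (int(c) for c in f3_counts)
    total = n_dd + n_het + n_other
    if total == 0:
        return None
    p_hat = (2 * n_dd + n_het) / (2 * total)
    return float(np.clip(2 * p_hat - male_transmission, 0.0, 1.0))


def harden_genotype_calls(marker_probs, threshold: float = 0.8):
    """Hard genotype calls from probability triples: argmax class iff its
    probability strictly exceeds ``threshold``, else None (missing).

    Accepts a single triple or an array (..., 3) over (GG, NG, NN); returns
    a string / object array of the same leading shape.
    """
    arr = np.asarray(marker_probs, dtype=float)
    if arr.shape[-1] != 3:
        raise ValueError("probability triples expected")
    if not np.allclose(arr.sum(axis=-1), 1.0, atol=1e-6):
        raise ValueError("genotype probabilities must sum to 1")
    flat = arr.reshape(-1, 3)
    best = flat.argmax(axis=1)
    calls = np.where(
        flat[np.arange(len(flat)), best] > threshold,
        np.array(GENO_CLASSES, dtype=object)[best],
        None,
    )
    if arr.ndim == 1:
        return calls[0]
    return calls.reshape(arr.shape[:-1])


def _rss(y: np.ndarray, X: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def lod_scan(
    panel: F2Panel,
    min_family: int = 12,
    max_missing: float = 0.5,
    cofactor: bool = True,
    call_threshold: float = 0.8,
    male_transmission: float = 0.5,
) -> LodProfile:
    """Genome scan for drive-modifier loci by regression on genotype
    probabilities.

    Individuals are retained if their %D_fem is based on at least
    ``min_family`` F3 progeny and fewer than ``max_missing`` of their
    hardened marker calls are missing.  Per marker, nested least-squares
    models (intercept [+ MDL11 cofactor] vs the same + expected G-allele
    dosage) give LOD = (n/2) log10(RSS0/RSS1); markers without genotype
    variation among retained individuals score 0 and are flagged.
    """
    pheno = panel.pct_d_fem(male_transmission)
    calls = harden_genotype_calls(panel.probs, call_threshold)
    missing_frac = (calls == None).mean(axis=1)  # noqa: E711 (object array)
    keep = (panel.n_f3 >= min_family) & (missing_frac < max_missing) & np.isfinite(pheno)
    n = int(keep.sum())
    if n < 20:
        raise ValueError(f"only {n} eligible F2 individuals after filtering")
    y = pheno[keep]
    dosage_all = 2.0 * panel.probs[keep, :, 0] + panel.probs[keep, :, 1]
    cof = (panel.mdl11[keep] == "Dd").astype(float)
    base_cols = [np.ones(n)] + ([cof] if cofactor else [])
    X0 = np.column_stack(base_cols)
    rss0 = _rss(y, X0)
    lod = np.zeros(len(panel.markers))
    flags = []
    if rss0 <= 1e-12 * n:  # phenotype fully explained by the null model
        return LodProfile(
            markers=panel.markers.reset_index(drop=True), lod=lod,
            smoothed=smooth_lod(lod), cofactor=cofactor, n_used=n,
            flags=["null-model-saturated"],
        )
    for j in range(len(panel.markers)):
        d = dosage_all[:, j]
        if np.ptp(d) < 1e-12:
            flags.append(str(panel.markers["marker"].iloc[j]))
            continue
        rss1 = _rss(y, np.column_stack(base_cols + [d]))
        if rss1 <= 0:
            rss1 = np.finfo(float).tiny
        lod[j] = max(0.0, (n / 2.0) * np.log10(rss0 / rss1))
    return LodProfile(
        markers=panel.markers.reset_index(drop=True), lod=lod,
        smoothed=smooth_lod(lod), cofactor=cofactor, n_used=n, flags=flags,
    )


def smooth_lod(lod, window: int = 4) -> np.ndarray:
    """Centered moving average with edge truncation.

    A window of w markers covers floor((w-1)/2) markers to the left and
    ceil((w-1)/2) to the right of each position; at the edges the available
    part of the window is used.  A window larger than the trace returns the
    global mean everywhere; window 1 is the identity.
    """
    arr = np.asarray(lod, dtype=float)
    if window < 1:
        raise ValueError("window must be >= 1")
    left = (window - 1) // 2
    right = window - 1 - left
    out = np.empty_like(arr)
    for i in range(arr.size):
        lo = max(0, i - left)
        hi = min(arr.size, i + right + 1)
        out[i] = arr[lo:hi].mean()
    return out


def two_way_anova(pheno, factor_a, factor_b) -> pd.DataFrame:
    """Two-way factorial ANOVA (Type-II sums of squares) of the drive
    phenotype on two categorical factors (e.g. CenH3A genotype x MDL11).

    Returns a table with rows factor_a, factor_b, interaction, residual and
    columns sum_sq, df, F, p.  When an empty factor-level cell makes the
    interaction inestimable, the interaction row is NaN-flagged and main
    effects come from the additive model.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = pd.DataFrame(
        {"y": np.asarray(pheno, dtype=float),
         "a": pd.Categorical(factor_a), "b": pd.Categorical(factor_b)}
    )
    if df["a"].nunique() < 2 or df["b"].nunique() < 2:
        raise ValueError("each factor needs at least two levels")
    cells = df.groupby(["a", "b"], observed=False).size()
    full_cells = (cells > 0).all()
    formula = "y ~ C(a) * C(b)" if full_cells else "y ~ C(a) + C(b)"
    fit = smf.ols(formula, data=df).fit()
    if fit.df_resid < 1:
        raise ValueError("no residual degrees of freedom")
    table = sm.stats.anova_lm(fit, typ=2)
    out = pd.DataFrame(
        index=["factor_a", "factor_b", "interaction", "residual"],
        columns=["sum_sq", "df", "F", "p"], dtype=float,
    )
    out.loc["factor_a"] = [
        table.loc["C(a)", "sum_sq"], table.loc["C(a)", "df"],
        table.loc["C(a)", "F"], table.loc["C(a)", "PR(>F)"],
    ]
    out.loc["factor_b"] = [
        table.loc["C(b)", "sum_sq"], table.loc["C(b)", "df"],
        table.loc["C(b)", "F"], table.loc["C(b)", "PR(>F)"],
    ]
    if full_cells:
        out.loc["interaction"] = [
            table.loc["C(a):C(b)", "sum_sq"], table.loc["C(a):C(b)", "df"],
            table.loc["C(a):C(b)", "F"], table.loc["C(a):C(b)", "PR(>F)"],
        ]
    out.loc["residual"] = [
        table.loc["Residual", "sum_sq"], table.loc["Residual", "df"],
        np.nan, np.nan,
    ]
    out.attrs["interaction_estimable"] = bool(full_cells)
    return out


# ---------------------------------------------------------------------------
# TSV interfaces
# ---------------------------------------------------------------------------

def read_f2_panel(probs_tsv, f3_tsv, map_tsv) -> F2Panel:
    """Assemble an :class:`F2Panel` from its three TSV inputs.

    ``probs_tsv``: f2_id, mdl11, marker, p_GG, p_NG, p_NN (long form);
    ``f3_tsv``: f2_id, n_DD, n_Dhet, n_other;
    ``map_tsv``: marker, chrom, cM (scan order).
    """
    probs = pd.read_csv(probs_tsv, sep="\t", dtype={"f2_id": str, "marker": str})
    f3 = pd.read_csv(f3_tsv, sep="\t", dtype={"f2_id": str})
    mmap = pd.read_csv(map_tsv, sep="\t", dtype={"marker": str, "chrom": str})
    f2_ids = list(f3["f2_id"])
    markers = list(mmap["marker"])
    mdl11 = (
        probs.drop_duplicates("f2_id").set_index("f2_id")["mdl11"].reindex(f2_ids)
    )
    wide = probs.set_index(["f2_id", "marker"])
    arr = np.full((len(f2_ids), len(markers), 3), 1.0 / 3.0)
    for i, fid in enumerate(f2_ids):
        for j, mk in enumerate(markers):
            try:
                row = wide.loc[(fid, mk)]
            except KeyError:
                continue
            arr[i, j] = [row["p_GG"], row["p_NG"], row["p_NN"]]
    counts = f3[["n_DD", "n_Dhet", "n_other"]].to_numpy()
    return F2Panel(
        f2_ids=f2_ids, mdl11=mdl11.to_numpy(), markers=mmap,
        probs=arr, f3_counts=counts,
    )


def write_f2_panel(panel: F2Panel, probs_tsv, f3_tsv, map_tsv) -> None:
    rows = []
    for i, fid in enumerate(panel.f2_ids):
        for j, mk in enumerate(panel.markers["marker"]):
            p = panel.probs[i, j]
            rows.append((fid, panel.mdl11[i], mk, p[0], p[1], p[2]))
    pd.DataFrame(
        rows, columns=["f2_id", "mdl11", "marker", "p_GG", "p_NG", "p_NN"]
    ).to_csv(probs_tsv, sep="\t", index=False)
    pd.DataFrame(
        {
            "f2_id": panel.f2_ids,
            "n_DD": panel.f3_counts[:, 0],
            "n_Dhet": panel.f3_counts[:, 1],
            "n_other": panel.f3_counts[:, 2],
        }
    ).to_csv(f3_tsv, sep="\t", index=False)
    panel.markers.to_csv(map_tsv, sep="\t", index=False)
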
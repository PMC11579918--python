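"""Signal-peptide cleavage efficiency from band intensities, with statistics.

Cleavage efficiency is computed from densitometry band intensities as

    cleavage (%) = cleaved * 100 / (cleaved + full-length)

which makes it invariant to the arbitrary units of the imager.  Profiles
plot mean +/- sample SD of replicate cleavage percentages against the
number of N-terminal extension residues (N-length).  Profiles are compared
point-by-point with two-tailed two-sample t tests (Student pooled-variance
or Welch), annotated with the conventional significance ladder
(n.s. > 0.05, * <= 0.05, ** <= 0.01, *** <= 0.001, **** <= 0.0001).
Raw p-values are always reported; a Holm-adjusted column is added for
transparency but never replaces them.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BAND_COLUMNS",
    "cleavage_percent",
    "read_band_table",
    "write_band_table",
    "build_profile",
    "compare_profiles",
    "star_annotation",
]

BAND_COLUMNS = ["construct", "n_length", "strain", "replicate", "cleaved", "full"]

_STAR_LADDER = [(1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*")]


def cleavage_percent(cleaved: float, full_length: float) -> float:
    """cleaved * 100 / (cleaved + full_length); errors if both are zero."""
    cleaved = float(cleaved)
    full_length = float(full_length)
    if cleaved < 0 or full_length < 0:
        raise ValueError("band intensities must be non-negative")
    total = cleaved + full_length
    if total == 0:
        raise ValueError("cleaved and full-length intensities are both zero")
    return cleaved * 100.0 / total


def star_annotation(p: float) -> str:
    """Significance stars by the <=-threshold ladder; 'n.s.' above 0.05."""
    for threshold, star in _STAR_LADDER:
        if p <= threshold:
            return star
    return "n.s."


def read_band_table(path: str | Path) -> pd.DataFrame:
    """Read a tab-separated band-intensity table with the standard header."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in BAND_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"band table {path} missing columns {missing}")
    return df


def write_band_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    return path


def _percent_column(df: pd.DataFrame) -> pd.Series:
    totals = df["cleaved"] + df["full"]
    if (totals <= 0).any():
        raise ValueError("some measurements have zero total intensity")
    return df["cleaved"] * 100.0 / totals


def build_profile(measurements: pd.DataFrame, strain: str | None = None) -> pd.DataFrame:
    """Mean/SD cleavage profile over N-length for one strain.

    Returns a frame with columns ``n_length, mean, sd, n`` sorted by
    N-length; SD is the n-1 sample standard deviation.  Mixing strains
    without naming one is an error; single-replicate points report SD 0
    with a warning.
    """
    df = measurements.copy()
    strains = df["strain"].unique()
    if strain is None:
        if len(strains) > 1:
            raise ValueError(
                f"table mixes strains {sorted(strains)}; pass `strain=` explicitly"
            )
        strain = strains[0]
    df = df[df["strain"] == strain]
    if df.empty:
        raise ValueError(f"no measurements for strain {strain!r}")
    df = df.assign(pct=_percent_column(df))
    rows = []
    for nl, grp in df.groupby("n_length"):
        vals = grp["pct"].to_numpy()
        if len(vals) == 1:
            warnings.warn(
                f"strain {strain}, N-length {nl}: single replicate, SD reported as 0"
            )
            sd = 0.0
        else:
            sd = float(vals.std(ddof=1))
        rows.append({"n_length": int(nl), "mean": float(vals.mean()),
                     "sd": sd, "n": len(vals)})
    out = pd.DataFrame(rows).sort_values("n_length").reset_index(drop=True)
    out.attrs["strain"] = strain
    return out


def compare_profiles(
    a: pd.DataFrame,
    b: pd.DataFrame,
    test: str = "welch",
    strain_a: str | None = None,
    strain_b: str | None = None,
) -> pd.DataFrame:
    """Point-by-point two-tailed t tests between two replicate-level tables.

    ``test='welch'`` applies the Welch-Satterthwaite correction (unequal
    variances); ``'student'`` is the pooled-variance test.  N-lengths with
    fewer than two replicates in either group are skipped with a warning.
    Returns columns ``n_length, t_statistic, degrees_of_freedom, p_value,
    p_holm, star``.
    """
    if test not in ("welch", "student"):
        raise ValueError("test must be 'welch' or 'student'")

    def _prep(df: pd.DataFrame, strain: str | None) -> pd.DataFrame:
        if strain is not None:
            df = df[df["strain"] == strain]
        elif df["strain"].nunique() > 1:
            raise ValueError("table mixes strains; pass strain_a/strain_b")
        return df.assign(pct=_percent_column(df))

    da, db = _prep(a, strain_a), _prep(b, strain_b)
    shared = sorted(set(da["n_length"]) & set(db["n_length"]))
    rows = []
    for nl in shared:
        xa = da.loc[da["n_length"] == nl, "pct"].to_numpy()
        xb = db.loc[db["n_length"] == nl, "pct"].to_numpy()
        if len(xa) < 2 or len(xb) < 2:
            warnings.warn(
                f"N-length {nl}: fewer than two replicates in a group; skipped"
            )
            continue
        res = stats.ttest_ind(xa, xb, equal_var=(test == "student"))
        rows.append(
            {
                "n_length": int(nl),
                "t_statistic": float(res.statistic),
                "degrees_of_freedom": float(res.df),
                "p_value": float(res.pvalue),
            }
        )
    out = pd.DataFrame(rows)
    if out.empty:
        return out.reindex(
            columns=["n_length", "t_statistic", "degrees_of_freedom",
                     "p_value", "p_holm", "star"]
        )
    out["p_holm"] = _holm(out["p_value"].to_numpy())
    out["star"] = [star_annotation(p) for p in out["p_value"]]
    return out


def welch_type1_calibration(
    n_simulations: int = 10_000,
    n_replicates: int = 6,
    planted: float = 50.0,
    cv: float = 0.1,
    alpha: float = 0.05,
    seed: int = 0,
    total_intensity: float = 1000.0,
) -> float:
    """Empirical type-I error of the per-point Welch test under the null.

    Simulates pairs of replicate groups from the same lognormal
    band-intensity model as :func:`memthick.synthetic.generate_band_table`
    (identical planted cleavage in both groups), applies the two-tailed
    Welch test to the cleavage percentages, and returns the fraction of
    simulations with p <= alpha.  A calibrated test returns ~alpha.
    """
    if cv <= 0:
        raise ValueError("cv must be > 0 for a meaningful null simulation")
    rng = np.random.default_rng(seed)
    sigma2 = np.log(1.0 + cv ** 2)
    sigma = np.sqrt(sigma2)
    base_c = total_intensity * planted / 100.0
    base_f = total_intensity * (1.0 - planted / 100.0)

    def _group() -> np.ndarray:
        f = np.exp(rng.normal(-sigma2 / 2.0, sigma,
                              size=(n_replicates, n_simulations, 2)))
        c = base_c * f[..., 0]
        fl = base_f * f[..., 1]
        return c * 100.0 / (c + fl)

    res = stats.ttest_ind(_group(), _group(), axis=0, equal_var=False)
    return float(np.mean(res.pvalue <= alpha))


def _holm(p: np.ndarray) -> np.ndarray:
    """Holm step-down adjusted p-values (reported alongside raw, never instead)."""
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj
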
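"""Post-hoc analysis: stimulation features, discrimination statistics,
standard deviational ellipses, and an ideal-observer classifier.

Per trial, four features summarize what the stimulation (and, under glove
control, the subject's own hand) could convey:

* onset_lag — time from grasp-command onset to the first nonzero commanded
  amplitude; under constant-velocity closure this is a proxy for object
  size (larger objects are contacted sooner).
* peak_amp — maximum commanded amplitude (mA).
* rate_of_change — mean slope of the commanded amplitude from stimulation
  onset to its first peak (mA/s); under constant-velocity closure a proxy
  for object compliance.
* aperture_at_onset — hand aperture (deg) when stimulation begins.

The statistical battery mirrors forced-choice psychophysics practice: exact
upper-tail binomial tests against chance, one-way MANOVA (Wilks' lambda)
over the feature set, per-feature ANOVA with Tukey-HSD post-hocs, and 1-SD
standard deviational ellipses with a pairwise overlap audit. A Gaussian
nearest-centroid ideal observer quantifies the information actually present
in a feature subset, independent of human perceptual limits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .grasp_sim import EMG_SCHEME, GLOVE_SCHEME, GraspTrace
from .stim_encoder import StimTrace
from .task_design import COMPLIANCE_ORDER, SIZE_ORDER

FEATURE_COLS = ("onset_lag", "peak_amp", "rate_of_change", "aperture_at_onset")

# The prosthesis aperture is imperceptible to the user under EMG control, so
# the observer sees stimulation-only features there; under glove control the
# glove is the subject's own hand, whose aperture is proprioceptively known.
SCHEME_FEATURES = {
    GLOVE_SCHEME: ("aperture_at_onset", "onset_lag", "peak_amp", "rate_of_change"),
    EMG_SCHEME: ("onset_lag", "peak_amp", "rate_of_change"),
}


@dataclass
class FeatureVector:
    onset_lag: float | None  # s
    peak_amp: float | None  # mA
    rate_of_change: float | None  # mA/s
    aperture_at_onset: float | None  # deg
    size_class: str
    compliance_class: str
    null_reason: str | None = None  # set (and features None) for no-contact trials


@dataclass
class BinomialResult:
    n: int
    k: int
    p0: float
    accuracy: float
    p_value: float
    alternative: str = "greater"


@dataclass
class EllipseParams:
    centroid: tuple[float, float]
    semi_axes: tuple[float, float]  # (a, b), a >= b, at n_std standard deviations
    orientation: float  # radians, major-axis angle in (-pi/2, pi/2]
    pearson_r: float
    n_std: float = 1.0


@dataclass
class DiscriminationResult:
    classes: list[str]
    confusion: np.ndarray  # K x K counts, rows = true class
    per_class_accuracy: dict[str, float]
    overall_accuracy: float
    per_class_binomial: dict[str, BinomialResult]
    overall_binomial: BinomialResult
    n_null_excluded: int = 0


def _detect_command_onset(grasp: GraspTrace, glove_vel_eps: float = 5.0) -> int | None:
    """Index of grasp-command onset: first envelope threshold crossing (EMG)
    or first sample with closing velocity beyond ``glove_vel_eps`` deg/s."""
    if grasp.scheme == EMG_SCHEME:
        thr = grasp.command_threshold
        if thr is None:
            raise ValueError("EMG trace lacks its command threshold")
        idx = np.nonzero(grasp.command >= thr)[0]
        return int(idx[0]) if idx.size else None
    dt = float(grasp.time[1] - grasp.time[0]) if grasp.time.size > 1 else 0.02
    vel = np.diff(grasp.aperture) / dt
    idx = np.nonzero(vel < -glove_vel_eps)[0]
    return int(idx[0]) + 1 if idx.size else None


def extract_features(
    grasp: GraspTrace, stim: StimTrace, glove_vel_eps: float = 5.0,
    peak_frac: float = 0.98,
) -> FeatureVector:
    """Per-trial stimulation features; null (None) features with a reason
    code when stimulation never turned on.

    The rise time ends at the *first* sample reaching ``peak_frac`` of the
    maximum amplitude: sensor noise on the force plateau makes the global
    argmax wander arbitrarily late, which would bias the rate of change
    toward zero.
    """
    if grasp.time.size != stim.time.size:
        raise ValueError("grasp and stimulation traces are not on the same grid")
    labels = dict(size_class=grasp.obj.size_class, compliance_class=grasp.obj.compliance_class)
    nz = np.nonzero(stim.amplitude > 0)[0]
    if nz.size == 0:
        return FeatureVector(None, None, None, None, **labels, null_reason="no_stimulation")
    cmd_idx = _detect_command_onset(grasp, glove_vel_eps)
    if cmd_idx is None:
        return FeatureVector(None, None, None, None, **labels, null_reason="no_command_onset")
    i_on = int(nz[0])
    t = grasp.time
    dt = float(t[1] - t[0]) if t.size > 1 else 0.02
    peak = float(stim.amplitude.max())
    peak_idx = int(np.nonzero(stim.amplitude >= peak_frac * peak)[0][0])
    rise = max(t[peak_idx] - t[i_on], dt)  # one-sample floor for instant peaks
    rate = (float(stim.amplitude[peak_idx]) - float(stim.amplitude[i_on])) / rise
    return FeatureVector(
        onset_lag=float(t[i_on] - t[cmd_idx]),
        peak_amp=peak,
        rate_of_change=float(rate),
        aperture_at_onset=float(grasp.aperture[i_on]),
        **labels,
    )


def features_table(pairs: Sequence[tuple[GraspTrace, StimTrace]]) -> pd.DataFrame:
    rows = []
    for i, (grasp, stim) in enumerate(pairs):
        fv = extract_features(grasp, stim)
        rows.append(
            {
                "trial_index": i,
                "size_class": fv.size_class,
                "compliance_class": fv.compliance_class,
                "onset_lag": fv.onset_lag,
                "peak_amp": fv.peak_amp,
                "rate_of_change": fv.rate_of_change,
                "aperture_at_onset": fv.aperture_at_onset,
                "null_reason": fv.null_reason,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Statistics


def binomial_above_chance(
    k: int, n: int, p0: float, alternative: str = "greater"
) -> BinomialResult:
    """Exact binomial test of k successes in n trials against chance p0.

    One-sided (upper tail) by default — the null is that accuracy is no
    better than chance; ``alternative='two-sided'`` is available for
    sensitivity analysis. p-values come from exact summation of the
    binomial mass, never a normal approximation.
    """
    if not 0 < p0 < 1:
        raise ValueError("p0 must lie in (0, 1)")
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    p = float(stats.binomtest(k, n, p0, alternative=alternative).pvalue)
    return BinomialResult(
        n=n, k=k, p0=p0, accuracy=k / n if n else math.nan, p_value=p,
        alternative=alternative,
    )


def feature_manova(
    df: pd.DataFrame,
    feature_cols: Sequence[str],
    factor: str,
) -> dict:
    """One-way MANOVA (Wilks' lambda) of the feature set against one factor.

    Lambda = det(W) / det(W + B) from the within- and between-group scatter
    matrices, with Rao's F approximation for the p-value. Rows with missing
    features are dropped.
    """
    data = df.dropna(subset=list(feature_cols))
    groups = [g[list(feature_cols)].to_numpy(float) for _, g in data.groupby(factor)]
    if len(groups) < 2:
        raise ValueError(f"factor {factor!r} needs >= 2 levels with data")
    p_dim = len(feature_cols)
    n_total = sum(len(g) for g in groups)
    if any(len(g) <= p_dim for g in groups):
        raise ValueError("need more observations than feature dimensions per cell")
    grand = data[list(feature_cols)].to_numpy(float).mean(axis=0)
    W = np.zeros((p_dim, p_dim))
    B = np.zeros((p_dim, p_dim))
    for g in groups:
        mu = g.mean(axis=0)
        dev = g - mu
        W += dev.T @ dev
        d = (mu - grand)[:, None]
        B += len(g) * (d @ d.T)
    detW = np.linalg.det(W)
    detT = np.linalg.det(W + B)
    if detW <= 0 or detT <= 0:
        corr = np.corrcoef(data[list(feature_cols)].to_numpy(float), rowvar=False)
        bad = [
            (feature_cols[i], feature_cols[j])
            for i in range(p_dim)
            for j in range(i + 1, p_dim)
            if abs(corr[i, j]) > 0.999
        ]
        raise ValueError(f"singular within-class scatter; collinear features: {bad}")
    lam = detW / detT
    g_lvls = len(groups)
    nu_h = g_lvls - 1
    nu_e = n_total - g_lvls
    denom = p_dim**2 + nu_h**2 - 5
    t = math.sqrt((p_dim**2 * nu_h**2 - 4) / denom) if denom > 0 else 1.0
    df1 = p_dim * nu_h
    w = nu_e + nu_h - (p_dim + nu_h + 1) / 2
    df2 = w * t - (p_dim * nu_h - 2) / 2
    lam_t = lam ** (1.0 / t)
    F = (1 - lam_t) / lam_t * df2 / df1
    p = float(stats.f.sf(F, df1, df2))
    return {"factor": factor, "wilks_lambda": float(lam), "F": float(F),
            "df1": float(df1), "df2": float(df2), "p_value": p, "n": int(n_total)}


def anova_tukey(values: np.ndarray, labels: Sequence[str], alpha: float = 0.05) -> dict:
    """One-way ANOVA plus all-pairs Tukey-HSD with family-wise adjusted p."""
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    keep = np.isfinite(values)
    values, labels = values[keep], labels[keep]
    lvls = pd.unique(labels)
    groups = [values[labels == lv] for lv in lvls]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    if all(np.allclose(g, g[0]) for g in groups):
        raise ValueError("zero within-group variance everywhere")
    F, p = stats.f_oneway(*groups)
    hsd = pairwise_tukeyhsd(values, labels, alpha=alpha)
    table = pd.DataFrame(
        data=hsd.summary().data[1:], columns=hsd.summary().data[0]
    )
    return {"F": float(F), "p_value": float(p), "tukey": table}


def sd_ellipse(x: np.ndarray, y: np.ndarray, n_std: float = 1.0) -> EllipseParams:
    """Standard deviational ellipse of a bivariate sample.

    Centroid at the sample means; axes and orientation from the
    eigendecomposition of the 2x2 sample covariance, scaled by ``n_std``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired points")
    cov = np.cov(x, y)
    if cov[0, 0] == 0 and cov[1, 1] == 0:
        raise ValueError("zero variance in both coordinates")
    evals, evecs = np.linalg.eigh(cov)  # ascending
    a = n_std * math.sqrt(max(evals[1], 0.0))
    b = n_std * math.sqrt(max(evals[0], 0.0))
    major = evecs[:, 1]
    theta = math.atan2(major[1], major[0])
    if theta <= -math.pi / 2:
        theta += math.pi
    elif theta > math.pi / 2:
        theta -= math.pi
    denom = math.sqrt(cov[0, 0] * cov[1, 1])
    r = cov[0, 1] / denom if denom > 0 else 0.0
    return EllipseParams(
        centroid=(float(x.mean()), float(y.mean())),
        semi_axes=(a, b), orientation=theta, pearson_r=float(r), n_std=n_std,
    )


def _ellipse_boundary(e: EllipseParams, n_points: int) -> np.ndarray:
    phi = np.linspace(0.0, 2 * math.pi, n_points, endpoint=False)
    a, b = e.semi_axes
    pts = np.stack([a * np.cos(phi), b * np.sin(phi)])
    c, s = math.cos(e.orientation), math.sin(e.orientation)
    rot = np.array([[c, -s], [s, c]])
    return (rot @ pts).T + np.asarray(e.centroid)


def _contains(e: EllipseParams, pts: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    c, s = math.cos(e.orientation), math.sin(e.orientation)
    rel = pts - np.asarray(e.centroid)
    u = c * rel[:, 0] + s * rel[:, 1]
    v = -s * rel[:, 0] + c * rel[:, 1]
    a, b = e.semi_axes
    if b <= tol:  # degenerate: a segment along the major axis
        return (np.abs(v) <= max(a * 1e-6, tol)) & (np.abs(u) <= a + tol)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0 + tol


def ellipse_overlap(e1: EllipseParams, e2: EllipseParams, n_points: int = 720) -> bool:
    """True iff the two (filled) 1-SD ellipse regions intersect; boundary
    tangency counts as overlap. Decided by dense boundary sampling plus
    containment tests (covers one-inside-the-other)."""
    c1 = np.asarray([e1.centroid])
    c2 = np.asarray([e2.centroid])
    if _contains(e1, c2).any() or _contains(e2, c1).any():
        return True
    if _contains(e2, _ellipse_boundary(e1, n_points)).any():
        return True
    return bool(_contains(e1, _ellipse_boundary(e2, n_points)).any())


# ---------------------------------------------------------------------------
# Ideal observer


def _class_order(classes: Sequence[str]) -> list[str]:
    for order in (SIZE_ORDER, COMPLIANCE_ORDER):
        if set(classes) <= set(order):
            return [c for c in order if c in set(classes)]
    return sorted(set(classes))


def ideal_observer(
    train: pd.DataFrame,
    test: pd.DataFrame,
    target_label: str,
    feature_cols: Sequence[str],
) -> DiscriminationResult:
    """Gaussian nearest-centroid classifier with pooled covariance.

    A deliberately simple observer: it lower-bounds the information a
    subject attending to stimulation dynamics could use, without modeling
    perceptual thresholds. Null-feature trials are excluded and counted.
    """
    cols = list(feature_cols)
    tr = train.dropna(subset=cols)
    te = test.dropna(subset=cols)
    n_null = (len(train) - len(tr)) + (len(test) - len(te))
    classes = _class_order(tr[target_label].unique())
    if len(classes) < 2:
        raise ValueError("need >= 2 classes in the training set")
    missing = set(te[target_label].unique()) - set(classes)
    if missing:
        raise ValueError(f"test classes absent from training set: {sorted(missing)}")

    X_tr = tr[cols].to_numpy(float)
    means = {c: tr.loc[tr[target_label] == c, cols].to_numpy(float).mean(axis=0) for c in classes}
    pooled = np.zeros((len(cols), len(cols)))
    dof = 0
    for c in classes:
        g = tr.loc[tr[target_label] == c, cols].to_numpy(float)
        dev = g - means[c]
        pooled += dev.T @ dev
        dof += len(g) - 1
    pooled = pooled / max(dof, 1) + 1e-9 * np.eye(len(cols)) * max(np.trace(pooled / max(dof, 1)), 1.0)
    prec = np.linalg.inv(pooled)

    X_te = te[cols].to_numpy(float)
    d2 = np.stack(
        [np.einsum("ij,jk,ik->i", X_te - means[c], prec, X_te - means[c]) for c in classes],
        axis=1,
    )
    pred = np.asarray(classes)[np.argmin(d2, axis=1)]
    true = te[target_label].to_numpy()

    k_cls = len(classes)
    conf = np.zeros((k_cls, k_cls), dtype=int)
    idx = {c: i for i, c in enumerate(classes)}
    for t_lbl, p_lbl in zip(true, pred):
        conf[idx[t_lbl], idx[p_lbl]] += 1
    p0 = 1.0 / k_cls
    per_acc, per_binom = {}, {}
    for c in classes:
        row = conf[idx[c]]
        n_c = int(row.sum())
        k_c = int(row[idx[c]])
        per_acc[c] = k_c / n_c if n_c else math.nan
        per_binom[c] = binomial_above_chance(k_c, n_c, p0) if n_c else BinomialResult(0, 0, p0, math.nan, 1.0)
    n_tot = int(conf.sum())
    k_tot = int(np.trace(conf))
    return DiscriminationResult(
        classes=classes,
        confusion=conf,
        per_class_accuracy=per_acc,
        overall_accuracy=k_tot / n_tot if n_tot else math.nan,
        per_class_binomial=per_binom,
        overall_binomial=binomial_above_chance(k_tot, n_tot, p0),
        n_null_excluded=int(n_null),
    )


# ---------------------------------------------------------------------------
# Full report


def _varying_factors(df: pd.DataFrame) -> list[str]:
    out = []
    for factor in ("size_class", "compliance_class"):
        if df[factor].nunique() > 1:
            out.append(factor)
    return out


def run_full_analysis(
    pairs: Sequence[tuple[GraspTrace, StimTrace]],
    queried_property: str | None = None,
    feature_subset: Sequence[str] | None = None,
    ellipse_pair: tuple[str, str] | None = None,
    n_std: float = 1.0,
) -> dict:
    """Feature table, MANOVA per varying factor, per-feature ANOVA + Tukey,
    standard deviational ellipses with an overlap matrix, and ideal-observer
    confusion matrices (split-half train/test by trial parity).

    Note: beyond Tukey's family-wise adjustment, p-values are reported
    uncorrected across the many ANOVAs.
    """
    if not pairs:
        raise ValueError("no trials to analyze")
    df = features_table(pairs)
    usable = df.dropna(subset=["onset_lag"])
    if usable.empty:
        raise ValueError("all trials have null features (no stimulation delivered)")
    scheme = pairs[0][0].scheme
    feats = tuple(feature_subset) if feature_subset else SCHEME_FEATURES[scheme]
    factors = _varying_factors(usable)
    if queried_property is None:
        queried_property = "size" if "size_class" in factors else "compliance"
    target = f"{queried_property}_class"

    report: dict = {
        "scheme": scheme,
        "queried_property": queried_property,
        "n_trials": int(len(df)),
        "n_null": int(df["null_reason"].notna().sum()),
        "feature_subset": list(feats),
        "uncorrected_anova_pvalues": True,
        "manova": {},
        "anova": {},
    }
    for factor in factors:
        try:
            report["manova"][factor] = feature_manova(usable, feats, factor)
        except ValueError as exc:
            report["manova"][factor] = {"error": str(exc)}
    for feat in feats:
        for factor in factors:
            try:
                res = anova_tukey(usable[feat].to_numpy(float), usable[factor])
            except ValueError as exc:
                report["anova"][f"{feat}~{factor}"] = {"error": str(exc)}
                continue
            report["anova"][f"{feat}~{factor}"] = {
                "F": res["F"], "p_value": res["p_value"],
                "tukey": res["tukey"].to_dict(orient="records"),
            }

    # Ellipses for the target classes on a feature pair.
    if ellipse_pair is None:
        ellipse_pair = (feats[0], feats[1] if len(feats) > 1 else feats[0])
    fx, fy = ellipse_pair
    classes = _class_order(usable[target].unique())
    ellipses: dict[str, EllipseParams] = {}
    for c in classes:
        g = usable[usable[target] == c]
        if len(g) >= 3:
            try:
                ellipses[c] = sd_ellipse(g[fx].to_numpy(float), g[fy].to_numpy(float), n_std)
            except ValueError:
                pass
    overlap = {
        f"{a}|{b}": ellipse_overlap(ellipses[a], ellipses[b])
        for i, a in enumerate(classes) for b in classes[i + 1:]
        if a in ellipses and b in ellipses
    }
    report["ellipses"] = {
        c: {
            "centroid": list(e.centroid), "semi_axes": list(e.semi_axes),
            "orientation_rad": e.orientation, "pearson_r": e.pearson_r,
        }
        for c, e in ellipses.items()
    }
    report["ellipse_pair"] = [fx, fy]
    report["ellipse_overlap"] = overlap

    # Split-half ideal observer (even trials train, odd trials test).
    train = df[df["trial_index"] % 2 == 0]
    test = df[df["trial_index"] % 2 == 1]
    if train[target].nunique() >= 2 and not test.dropna(subset=list(feats)).empty:
        disc = ideal_observer(train, test, target, feats)
        report["ideal_observer"] = discrimination_to_dict(disc)
    else:
        report["ideal_observer"] = None
    report["features"] = df
    return report


def discrimination_to_dict(d: DiscriminationResult) -> dict:
    return {
        "classes": d.classes,
        "confusion": d.confusion.tolist(),
        "per_class_accuracy": d.per_class_accuracy,
        "overall_accuracy": d.overall_accuracy,
        "chance": 1.0 / len(d.classes),
        "overall_binomial": {
            "n": d.overall_binomial.n, "k": d.overall_binomial.k,
            "p0": d.overall_binomial.p0, "p_value": d.overall_binomial.p_value,
        },
        "per_class_binomial": {
            c: {"n": b.n, "k": b.k, "p0": b.p0, "p_value": b.p_value}
            for c, b in d.per_class_binomial.items()
        },
        "n_null_excluded": d.n_null_excluded,
    }
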
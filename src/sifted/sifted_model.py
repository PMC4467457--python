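"""The SIFTED context model: predicting a TALE's energy matrix from its RVDs.

Each non-anchored (element, base) ddG value inferred from PBM data is one
regression observation.  The anchored (preferred-base) entries are exactly 0
by construction and carry no information, so they are excluded.  Features:

* an indicator for the (element type, base) pair, element type in
  {NTR, NI, HD, NN, NG} — the baseline specificity of each contact;
* for repeat rows only: repeat position p (1-based), ln p, target-site
  length L (bases), ln L, each interacted with the (type, base) indicator,
  so every repeat type has its own position and length response;
* indicators for the N-terminal neighbour type (NTR or a repeat) and the
  C-terminal neighbour type (a repeat or the CTR), interacted with
  (type, base).  The NTR row carries only C-side neighbour features (it has
  no N-terminal neighbour) and no position/length features.

Columns are standardized to mean 0 / variance 1 (constant columns dropped);
each row is weighted by 1 / (number of panel proteins sharing that protein's
nominal repeat length) so over-represented lengths do not dominate.

Fitting is a weighted Elastic Net (95% L1 / 5% L2) along a 100-value
log-spaced lambda path, with model complexity chosen by nested
cross-validation: an outer leave-one-protein-out loop and an inner
protein-grouped 5-fold loop share a single lambda selected by the one-
standard-error rule on bootstrapped MSE estimates; that same lambda is used
for every training set and for the final full-panel refit.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import ElasticNet

from .energy_model import BASES, BASE_INDEX, EnergyMatrix, PWM, canonical_anchors, em_to_pwm
from .tale_core import CTR, NTR, RVD_CODES, RVD_TO_BASE, TALEProtein

__all__ = [
    "FEATURE_SPEC_VERSION",
    "FeaturePanel",
    "ContextModel",
    "CVReport",
    "feature_names",
    "element_rows",
    "row_features",
    "build_feature_matrix",
    "elastic_net_path",
    "nested_cv",
    "predict_em",
    "neighbor_effect_log2ratio",
    "load_panel_tsv",
    "panel_to_tsv",
]

logger = logging.getLogger(__name__)

FEATURE_SPEC_VERSION = "sifted-features-v1"

ELEMENT_TYPES = (NTR,) + RVD_CODES
ANCHOR_BASE = {NTR: "T", **RVD_TO_BASE}
N_NEIGHBOURS = (NTR,) + RVD_CODES          # possible N-terminal neighbours
C_NEIGHBOURS = RVD_CODES + (CTR,)          # possible C-terminal neighbours


def _nonanchored(t: str) -> list[str]:
    return [b for b in BASES if b != ANCHOR_BASE[t]]


def feature_names(rvd_only: bool = False) -> list[str]:
    """The fixed, versioned feature order of the design matrix."""
    names = []
    for t in ELEMENT_TYPES:
        for b in _nonanchored(t):
            names.append(f"rvd[{t}:{b}]")
    if rvd_only:
        return names
    for t in RVD_CODES:
        for b in _nonanchored(t):
            for prefix in ("pos", "lnpos", "len", "lnlen"):
                names.append(f"{prefix}[{t}:{b}]")
    for t in RVD_CODES:
        for b in _nonanchored(t):
            for n in N_NEIGHBOURS:
                names.append(f"nnb[{t}:{b}|{n}]")
    for t in ELEMENT_TYPES:
        for b in _nonanchored(t):
            cands = C_NEIGHBOURS if t != NTR else RVD_CODES
            for c in cands:
                names.append(f"cnb[{t}:{b}|{c}]")
    return names


@dataclass(frozen=True)
class RowSpec:
    """One (element, base) observation slot of a protein."""

    element_index: int          # 0 = NTR, 1..k = repeats
    element_type: str
    base: str                   # the non-anchored base this row describes
    position: int | None        # 1-based repeat position; None for the NTR
    site_length: int            # target-site length in bases (repeats + 1)
    n_neighbour: str | None
    c_neighbour: str | None


def element_rows(protein: TALEProtein) -> list[RowSpec]:
    """All 3 * (k + 1) non-anchored observation slots of a protein."""
    k = protein.n_elements
    L = protein.site_length
    rows = []
    for b in _nonanchored(NTR):
        rows.append(RowSpec(0, NTR, b, None, L, None, protein.repeats[0]))
    for i, t in enumerate(protein.repeats, start=1):
        n_nb = NTR if i == 1 else protein.repeats[i - 2]
        c_nb = CTR if i == k else protein.repeats[i]
        for b in _nonanchored(t):
            rows.append(RowSpec(i, t, b, i, L, n_nb, c_nb))
    return rows


def row_features(row: RowSpec, names: list[str] | None = None) -> np.ndarray:
    """Raw (unstandardized) feature vector for one observation slot."""
    names = names if names is not None else feature_names()
    vals = dict.fromkeys(names, 0.0)
    t, b = row.element_type, row.base
    key = f"rvd[{t}:{b}]"
    if key not in vals:
        raise ValueError(f"unsupported element/base pair {t}:{b}")
    vals[key] = 1.0
    if t != NTR and row.position is not None:
        p, L = row.position, row.site_length
        for prefix, v in (
            ("pos", float(p)),
            ("lnpos", float(np.log(p))),
            ("len", float(L)),
            ("lnlen", float(np.log(L))),
        ):
            name = f"{prefix}[{t}:{b}]"
            if name in vals:
                vals[name] = v
    if row.n_neighbour is not None:
        name = f"nnb[{t}:{b}|{row.n_neighbour}]"
        if name in vals:
            vals[name] = 1.0
    if row.c_neighbour is not None:
        name = f"cnb[{t}:{b}|{row.c_neighbour}]"
        if name in vals:
            vals[name] = 1.0
    return np.array([vals[n] for n in names])


@dataclass
class FeaturePanel:
    """Design matrix, responses, weights and row metadata for a protein panel."""

    X: pd.DataFrame
    y: pd.Series
    weights: np.ndarray
    meta: pd.DataFrame
    proteins: dict[str, TALEProtein]


def build_feature_matrix(
    panel: list[tuple[TALEProtein, EnergyMatrix]],
    rvd_only: bool = False,
) -> FeaturePanel:
    """Assemble the regression data set from (protein, anchored EM) pairs.

    Rows are the non-anchored ddG entries; anchored entries (ddG = 0 by
    normalization) are removed.  Row weight = 1 / (# proteins of the same
    nominal length).
    """
    names = feature_names(rvd_only=rvd_only)
    length_counts: dict[float, int] = {}
    for protein, _ in panel:
        length_counts[protein.nominal_length] = length_counts.get(protein.nominal_length, 0) + 1

    rows, ys, ws, meta = [], [], [], []
    for protein, em in panel:
        if em.length != protein.site_length:
            raise ValueError(
                f"protein {protein.id}: EM length {em.length} != site length "
                f"{protein.site_length}"
            )
        em = em.anchored()
        w = 1.0 / length_counts[protein.nominal_length]
        for spec in element_rows(protein):
            j = spec.element_index
            rows.append(row_features(spec, names))
            ys.append(em.values[j, BASE_INDEX[spec.base]])
            ws.append(w)
            meta.append(
                {
                    "protein_id": protein.id,
                    "element_index": j,
                    "element_type": spec.element_type,
                    "base": spec.base,
                }
            )
    X = pd.DataFrame(np.array(rows), columns=names)
    return FeaturePanel(
        X=X,
        y=pd.Series(ys, name="ddg"),
        weights=np.array(ws),
        meta=pd.DataFrame(meta),
        proteins={p.id: p for p, _ in panel},
    )


# ---- standardization ----------------------------------------------------

@dataclass
class Standardizer:
    means: pd.Series
    scales: pd.Series

    @classmethod
    def fit(cls, X: pd.DataFrame) -> "Standardizer":
        means = X.mean(axis=0)
        scales = X.std(axis=0, ddof=0)
        constant = scales[scales == 0].index.tolist()
        if constant:
            logger.info("dropping %d constant feature columns: %s",
                        len(constant), constant[:8])
        keep = scales[scales > 0].index
        return cls(means=means[keep], scales=scales[keep])

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        cols = self.means.index
        return ((X[cols] - self.means) / self.scales).to_numpy()


# ---- elastic net --------------------------------------------------------

def _lambda_max(Xs: np.ndarray, y: np.ndarray, w: np.ndarray, l1_ratio: float) -> float:
    n = len(y)
    wn = w * n / w.sum()
    ybar = np.average(y, weights=wn)
    return float(np.max(np.abs(Xs.T @ (wn * (y - ybar)))) / (n * l1_ratio))


def elastic_net_path(
    Xs: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray,
    alpha: float = 0.95,
    n_lambda: int = 100,
    lambdas: np.ndarray | None = None,
    lambda_decades: float = 4.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weighted Elastic Net coefficients along a decreasing lambda path.

    Minimizes (1/2N) sum_i w_i (y_i - b0 - x_i' beta)^2
    + lambda * (alpha ||beta||_1 + (1 - alpha)/2 ||beta||_2^2).
    Returns (lambdas, coefficient matrix (n_lambda, p), intercepts).
    At the first path point (lambda_max) all non-intercept coefficients are 0.
    """
    y = np.asarray(y, dtype=float)
    if np.var(y) == 0:
        raise ValueError("response has zero variance; nothing to fit")
    if lambdas is None:
        lmax = _lambda_max(Xs, y, weights, max(alpha, 1e-3))
        lambdas = np.logspace(np.log10(lmax), np.log10(lmax) - lambda_decades, n_lambda)
    coefs = np.zeros((len(lambdas), Xs.shape[1]))
    intercepts = np.zeros(len(lambdas))
    model = ElasticNet(
        alpha=lambdas[0],
        l1_ratio=alpha,
        fit_intercept=True,
        warm_start=True,
        max_iter=20000,
        tol=1e-4,
    )
    for i, lam in enumerate(lambdas):
        model.set_params(alpha=float(lam))
        model.fit(Xs, y, sample_weight=weights)
        coefs[i] = model.coef_
        intercepts[i] = model.intercept_
    return np.asarray(lambdas), coefs, intercepts


def _fit_single(Xs, y, weights, lam, alpha):
    model = ElasticNet(alpha=float(lam), l1_ratio=alpha, fit_intercept=True,
                       max_iter=50000, tol=1e-6)
    model.fit(Xs, y, sample_weight=weights)
    return model.coef_.copy(), float(model.intercept_)


# ---- trained model ------------------------------------------------------

@dataclass
class ContextModel:
    """A trained SIFTED predictor: standardization stats + Elastic Net fit."""

    coefficients: pd.Series      # indexed by kept feature names
    intercept: float
    alpha: float
    lambda_chosen: float
    means: pd.Series
    scales: pd.Series
    feature_spec: str = FEATURE_SPEC_VERSION
    rvd_only: bool = False

    def predict_rows(self, X_raw: pd.DataFrame) -> np.ndarray:
        cols = self.coefficients.index
        Xs = ((X_raw[cols] - self.means[cols]) / self.scales[cols]).to_numpy()
        return self.intercept + Xs @ self.coefficients.to_numpy()

    # -- serialization: human-readable TSV ---------------------------------
    def to_tsv(self) -> str:
        buf = io.StringIO()
        buf.write(f"# feature_spec={self.feature_spec}\n")
        buf.write(f"# alpha={float(self.alpha)!r}\n")
        buf.write(f"# lambda={float(self.lambda_chosen)!r}\n")
        buf.write(f"# rvd_only={int(self.rvd_only)}\n")
        buf.write("feature\tcoefficient\tmean\tscale\n")
        buf.write(f"__intercept__\t{float(self.intercept)!r}\t0\t1\n")
        for name in self.coefficients.index:
            buf.write(
                f"{name}\t{float(self.coefficients[name])!r}\t"
                f"{float(self.means[name])!r}\t{float(self.scales[name])!r}\n"
            )
        return buf.getvalue()

    @classmethod
    def from_tsv(cls, text: str) -> "ContextModel":
        headers = {}
        for line in text.splitlines():
            if line.startswith("#") and "=" in line:
                k, v = line[1:].strip().split("=", 1)
                headers[k] = v
        df = pd.read_csv(io.StringIO(text), sep="\t", comment="#",
                         float_precision="round_trip")
        inter = float(df.loc[df["feature"] == "__intercept__", "coefficient"].iloc[0])
        df = df[df["feature"] != "__intercept__"].set_index("feature")
        return cls(
            coefficients=df["coefficient"].astype(float),
            intercept=inter,
            alpha=float(headers.get("alpha", "0.95")),
            lambda_chosen=float(headers.get("lambda", "0.0")),
            means=df["mean"].astype(float),
            scales=df["scale"].astype(float),
            feature_spec=headers.get("feature_spec", FEATURE_SPEC_VERSION),
            rvd_only=bool(int(headers.get("rvd_only", "0"))),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_tsv())

    @classmethod
    def load(cls, path) -> "ContextModel":
        with open(path) as fh:
            return cls.from_tsv(fh.read())


@dataclass
class CVReport:
    lambda_path: np.ndarray
    mse_mean: np.ndarray
    mse_se: np.ndarray
    chosen_lambda: float
    lambda_min_mse: float
    heldout: pd.DataFrame            # protein_id, element_index, base, y_true, y_pred
    heldout_ems: dict[str, EnergyMatrix]


def _protein_folds(ids: list[str], n_folds: int, rng: np.random.Generator) -> list[list[str]]:
    ids = list(ids)
    rng.shuffle(ids)
    return [ids[i::n_folds] for i in range(n_folds)]


def nested_cv(
    panel: list[tuple[TALEProtein, EnergyMatrix]],
    alpha: float = 0.95,
    n_lambda: int = 100,
    n_folds: int = 5,
    n_bootstrap: int = 1000,
    seed: int = 0,
    rvd_only: bool = False,
) -> tuple[ContextModel, CVReport]:
    """Train with nested CV: outer leave-one-protein-out, inner grouped 5-fold.

    A single lambda — the largest whose pooled inner-CV MSE is within one
    bootstrap standard error of the minimum — is shared by every training
    set, used to predict each held-out protein, and finally refit on the
    full panel to produce the deliverable model.
    """
    if len(panel) < n_folds + 1:
        raise ValueError(
            f"need >= {n_folds + 1} proteins for a meaningful inner "
            f"{n_folds}-fold CV, got {len(panel)}"
        )
    fp = build_feature_matrix(panel, rvd_only=rvd_only)
    std = Standardizer.fit(fp.X)
    Xs_all = std.transform(fp.X)
    y_all = fp.y.to_numpy()
    w_all = fp.weights
    pid = fp.meta["protein_id"].to_numpy()
    protein_ids = list(fp.proteins)
    rng = np.random.default_rng(seed)

    lmax = _lambda_max(Xs_all, y_all, w_all, alpha)
    lambdas = np.logspace(np.log10(lmax), np.log10(lmax) - 4.0, n_lambda)

    # inner CV: pooled held-out squared errors per lambda across all outer
    # iterations (each inner test fold is scored with models trained on the
    # remaining inner proteins)
    err_rows = []
    for held in protein_ids:
        inner_ids = [p for p in protein_ids if p != held]
        folds = _protein_folds(inner_ids, n_folds, rng)
        for fold in folds:
            if not fold:
                continue
            test_mask = np.isin(pid, fold)
            train_mask = ~test_mask & (pid != held)
            _, coefs, intercepts = elastic_net_path(
                Xs_all[train_mask], y_all[train_mask], w_all[train_mask],
                alpha=alpha, lambdas=lambdas,
            )
            preds = Xs_all[test_mask] @ coefs.T + intercepts[None, :]
            err_rows.append((y_all[test_mask, None] - preds) ** 2)
    errs = np.vstack(err_rows)                      # (n_heldout_rows, n_lambda)
    mse_mean = errs.mean(axis=0)

    boot_idx = rng.integers(0, errs.shape[0], size=(n_bootstrap, errs.shape[0]))
    boot_means = errs[boot_idx].mean(axis=1)        # (B, n_lambda)
    mse_se = boot_means.std(axis=0, ddof=1)

    i_min = int(np.argmin(mse_mean))
    lambda_min = float(lambdas[i_min])
    threshold = mse_mean[i_min] + mse_se[i_min]
    i_chosen = int(np.argmax(mse_mean <= threshold))  # first (largest) lambda within 1 SE
    chosen = float(lambdas[i_chosen])
    logger.info("lambda(min MSE)=%.4g, lambda(one-SE)=%.4g", lambda_min, chosen)

    # outer refits at the shared lambda -> held-out predictions per protein
    heldout_rows = []
    heldout_ems: dict[str, EnergyMatrix] = {}
    for held in protein_ids:
        train_mask = pid != held
        coef, inter = _fit_single(Xs_all[train_mask], y_all[train_mask],
                                  w_all[train_mask], chosen, alpha)
        pred = Xs_all[pid == held] @ coef + inter
        sub = fp.meta[pid == held].copy()
        sub["y_true"] = y_all[pid == held]
        sub["y_pred"] = pred
        heldout_rows.append(sub)
        fold_model = ContextModel(
            coefficients=pd.Series(coef, index=std.means.index),
            intercept=inter, alpha=alpha, lambda_chosen=chosen,
            means=std.means, scales=std.scales, rvd_only=rvd_only,
        )
        em, _ = predict_em(fp.proteins[held], fold_model)
        heldout_ems[held] = em
    heldout = pd.concat(heldout_rows, ignore_index=True)

    coef, inter = _fit_single(Xs_all, y_all, w_all, chosen, alpha)
    model = ContextModel(
        coefficients=pd.Series(coef, index=std.means.index),
        intercept=inter, alpha=alpha, lambda_chosen=chosen,
        means=std.means, scales=std.scales, rvd_only=rvd_only,
    )
    report = CVReport(
        lambda_path=lambdas, mse_mean=mse_mean, mse_se=mse_se,
        chosen_lambda=chosen, lambda_min_mse=lambda_min,
        heldout=heldout, heldout_ems=heldout_ems,
    )
    return model, report


# ---- prediction ---------------------------------------------------------

def predict_em(protein: TALEProtein, model: ContextModel) -> tuple[EnergyMatrix, PWM]:
    """Predict the anchored energy matrix and Boltzmann PWM of a protein."""
    names = feature_names(rvd_only=model.rvd_only)
    rows = element_rows(protein)
    X = pd.DataFrame(
        np.array([row_features(r, names) for r in rows]), columns=names
    )
    preds = model.predict_rows(X)
    anchors = canonical_anchors(protein)
    values = np.zeros((protein.site_length, 4))
    for r, v in zip(rows, preds):
        values[r.element_index, BASE_INDEX[r.base]] = v
    em = EnergyMatrix(values=values, anchors=anchors)
    return em, em_to_pwm(em)


def neighbor_effect_log2ratio(
    model: ContextModel,
    element_type: str,
    base: str,
    neighbour: str,
    side: str,
    position: int = 7,
    site_length: int = 15,
) -> float:
    """log2 ratio of the predicted PWM frequency of ``base`` at an element
    with vs without the named neighbour on the given side ("N" or "C").

    The whole column is re-predicted in both settings (all three non-anchored
    bases respond to the neighbour), then converted to Boltzmann frequencies.
    """
    if side not in ("N", "C"):
        raise ValueError("side must be 'N' or 'C'")
    if element_type not in ELEMENT_TYPES:
        raise ValueError(f"unknown element type {element_type!r}")
    if base not in _nonanchored(element_type):
        raise ValueError(f"{base!r} is the anchored base of {element_type} or invalid")
    if side == "N":
        if element_type == NTR:
            raise ValueError("the NTR has no N-terminal neighbour")
        if neighbour not in N_NEIGHBOURS:
            raise ValueError(f"invalid N-terminal neighbour {neighbour!r}")
    else:
        valid = C_NEIGHBOURS if element_type != NTR else RVD_CODES
        if neighbour not in valid:
            raise ValueError(f"invalid C-terminal neighbour {neighbour!r} for {element_type}")

    names = feature_names(rvd_only=model.rvd_only)
    pos = None if element_type == NTR else position

    def column(with_neighbour: bool) -> np.ndarray:
        ddg = []
        for b in _nonanchored(element_type):
            spec = RowSpec(
                element_index=0 if element_type == NTR else position,
                element_type=element_type,
                base=b,
                position=pos,
                site_length=site_length,
                n_neighbour=neighbour if (side == "N" and with_neighbour) else None,
                c_neighbour=neighbour if (side == "C" and with_neighbour) else None,
            )
            ddg.append(row_features(spec, names))
        X = pd.DataFrame(np.array(ddg), columns=names)
        return model.predict_rows(X)

    def freqs(ddg3: np.ndarray) -> dict[str, float]:
        col = {ANCHOR_BASE[element_type]: 0.0}
        col.update(dict(zip(_nonanchored(element_type), ddg3)))
        w = {b: np.exp(-col[b]) for b in BASES}
        tot = sum(w.values())
        return {b: w[b] / tot for b in BASES}

    p_with = freqs(column(True))[base]
    p_without = freqs(column(False))[base]
    return float(np.log2(p_with / p_without))


# ---- panel TSV I/O ------------------------------------------------------

def panel_to_tsv(panel: list[tuple[TALEProtein, EnergyMatrix]]) -> str:
    """One row per (protein, site position): protein_id, rvds, position, A..T."""
    lines = ["protein_id\trvds\tposition\tA\tC\tG\tT"]
    for protein, em in panel:
        rvds = protein.format()
        for j in range(em.length):
            vals = "\t".join(f"{v:.6g}" for v in em.values[j])
            lines.append(f"{protein.id}\t{rvds}\t{j}\t{vals}")
    return "\n".join(lines) + "\n"


def load_panel_tsv(path_or_buf) -> list[tuple[TALEProtein, EnergyMatrix]]:
    from .tale_core import parse_rvd_string

    df = pd.read_csv(path_or_buf, sep="\t")
    panel = []
    for pid, grp in df.groupby("protein_id", sort=False):
        protein = parse_rvd_string(str(grp["rvds"].iloc[0]), protein_id=str(pid))
        grp = grp.sort_values("position")
        values = grp[["A", "C", "G", "T"]].to_numpy(float)
        em = EnergyMatrix(values=values, anchors=canonical_anchors(protein))
        panel.append((protein, em))
    return panel
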
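"""Landmark-based facial morphometrics.

Nineteen named landmarks per face (pixel coordinates, origin top-left,
y increasing downward) are converted to fourteen traditional
interlandmark distance traits.  Downstream reductions follow the
standard morphometric toolbox:

* maximum-likelihood factor analysis with Kaiser-normalized varimax
  rotation, yielding the "outer" (face/forehead height, hair, beard)
  and "inner" (eyes, interocular span, mouth, philtrum) facial factors;
* canonical variate analysis (CVA) for group separation, via the
  eigenstructure of the pooled within-group vs. between-group scatter;
* PCA for unconstrained visualization.

Landmark files are read from TPS records (``LM=19`` blocks) or tidy CSV.
TPS uses a bottom-left origin, so y is negated on read/write; distances
are unaffected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.linalg
from sklearn.decomposition import FactorAnalysis

__all__ = [
    "LANDMARK_NAMES",
    "TRAIT_NAMES",
    "LandmarkSet",
    "TraitVector",
    "FactorModel",
    "CVAResult",
    "IncompleteLandmarksError",
    "SingularScatterError",
    "derive_traits",
    "fit_factors",
    "cva",
    "cva_loo_accuracy",
    "pca",
    "label_facial_factors",
    "load_landmarks",
    "save_landmarks_tps",
    "save_landmarks_csv",
]

#: The 19 facial landmarks, in canonical file order.
LANDMARK_NAMES = (
    "A",   # top of the head
    "B",   # right side of the face
    "C",   # left side of the face
    "D",   # end of chin
    "E1",  # outer side of right eye
    "E2",  # inner side of right eye
    "G1",  # outer side of left eye
    "G2",  # inner side of left eye
    "F",   # middle point of the reference cross
    "H",   # right side of the nose
    "I",   # left side of the nose
    "J",   # tip of the nose
    "K",   # left end of the mouth
    "L",   # middle point of the mouth on the reference line
    "M",   # right end of the mouth
    "N",   # top point of head hair
    "O1",  # right tip of side hair
    "O2",  # left tip of side hair
    "P",   # tip of the chin hair (beard)
)

#: The 14 distance traits, in canonical order.
TRAIT_NAMES = (
    "face_height",
    "face_width",
    "forehead_height",
    "eye_size",
    "nose_length",
    "nose_width",
    "mouth_width",
    "side_hair",
    "top_hair",
    "beard",
    "interocular",
    "eyes_to_mouth",
    "philtrum",
    "chin",
)


class IncompleteLandmarksError(ValueError):
    """A required landmark is missing from a landmark set."""


class SingularScatterError(np.linalg.LinAlgError):
    """Within-group scatter is singular; re-run with a ridge term."""


@dataclass
class LandmarkSet:
    """Nineteen named (x, y) points in pixel coordinates, origin top-left."""

    points: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        missing = [n for n in LANDMARK_NAMES if n not in self.points]
        if missing:
            raise IncompleteLandmarksError(f"missing landmark(s): {', '.join(missing)}")
        clean = {}
        for name in LANDMARK_NAMES:
            x, y = self.points[name]
            if not (np.isfinite(x) and np.isfinite(y)):
                raise ValueError(f"landmark {name} has non-finite coordinates")
            clean[name] = (float(x), float(y))
        self.points = clean

    def __getitem__(self, name: str) -> tuple[float, float]:
        return self.points[name]

    def as_array(self) -> np.ndarray:
        """(19, 2) coordinate array in canonical landmark order."""
        return np.array([self.points[n] for n in LANDMARK_NAMES], dtype=float)

    @classmethod
    def from_array(cls, coords: np.ndarray) -> "LandmarkSet":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (19, 2):
            raise ValueError(f"expected (19, 2) coordinates, got {coords.shape}")
        return cls({n: tuple(xy) for n, xy in zip(LANDMARK_NAMES, coords)})

    def transformed(self, matrix: np.ndarray | None = None,
                    offset: tuple[float, float] = (0.0, 0.0)) -> "LandmarkSet":
        """Apply an affine map (2x2 matrix then translation)."""
        coords = self.as_array()
        if matrix is not None:
            coords = coords @ np.asarray(matrix, dtype=float).T
        coords = coords + np.asarray(offset, dtype=float)
        return LandmarkSet.from_array(coords)


def _dist(lm: LandmarkSet, a: str, b: str) -> float:
    (xa, ya), (xb, yb) = lm[a], lm[b]
    return float(np.hypot(xa - xb, ya - yb))


@dataclass
class TraitVector:
    """The 14 interlandmark distance traits, in pixels."""

    face_height: float
    face_width: float
    forehead_height: float
    eye_size: float
    nose_length: float
    nose_width: float
    mouth_width: float
    side_hair: float
    top_hair: float
    beard: float
    interocular: float
    eyes_to_mouth: float
    philtrum: float
    chin: float

    def as_series(self) -> pd.Series:
        return pd.Series({n: getattr(self, n) for n in TRAIT_NAMES})

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in TRAIT_NAMES], dtype=float)


def derive_traits(lm: LandmarkSet, nose_convention: str = "as_printed") -> TraitVector:
    """Convert landmarks to the 14 distance traits.

    ``nose_convention`` selects the nose measurements: ``"as_printed"``
    uses nose length F–I and width H–J (the published trait list);
    ``"geometric"`` uses the geometrically natural length F–J and
    width H–I.
    """
    if nose_convention == "as_printed":
        nose_length = _dist(lm, "F", "I")
        nose_width = _dist(lm, "H", "J")
    elif nose_convention == "geometric":
        nose_length = _dist(lm, "F", "J")
        nose_width = _dist(lm, "H", "I")
    else:
        raise ValueError("nose_convention must be 'as_printed' or 'geometric'")
    return TraitVector(
        face_height=_dist(lm, "A", "D"),
        face_width=_dist(lm, "B", "C"),
        forehead_height=_dist(lm, "A", "F"),
        eye_size=(_dist(lm, "E1", "E2") + _dist(lm, "G1", "G2")) / 2.0,
        nose_length=nose_length,
        nose_width=nose_width,
        mouth_width=_dist(lm, "K", "M"),
        side_hair=(_dist(lm, "O1", "B") + _dist(lm, "C", "O2")) / 2.0,
        top_hair=_dist(lm, "N", "A"),
        beard=_dist(lm, "D", "P"),
        interocular=_dist(lm, "E2", "G2"),
        eyes_to_mouth=_dist(lm, "F", "L"),
        philtrum=_dist(lm, "I", "L"),
        chin=_dist(lm, "L", "D"),
    )


def traits_frame(landmarks: dict[str, LandmarkSet], **kwargs) -> pd.DataFrame:
    """Trait table (items x 14) from a mapping of landmark sets."""
    rows = {k: derive_traits(v, **kwargs).as_series() for k, v in landmarks.items()}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "image_id"
    return df[list(TRAIT_NAMES)]


# ---------------------------------------------------------------------------
# Factor analysis
# ---------------------------------------------------------------------------

def _varimax(loadings: np.ndarray, kaiser: bool = True,
             max_iter: int = 500, tol: float = 1e-10) -> np.ndarray:
    """Varimax rotation, optionally with Kaiser row normalization."""
    lam = loadings.copy()
    p, k = lam.shape
    if k < 2:
        return lam
    if kaiser:
        comm = np.sqrt((lam ** 2).sum(axis=1))
        comm = np.where(comm < 1e-12, 1.0, comm)
        lam = lam / comm[:, None]
    rot = np.eye(k)
    var_old = 0.0
    for _ in range(max_iter):
        lr = lam @ rot
        u, s, vt = np.linalg.svd(
            lam.T @ (lr ** 3 - lr @ np.diag((lr ** 2).sum(axis=0)) / p)
        )
        rot = u @ vt
        var_new = s.sum()
        if var_new - var_old < tol:
            break
        var_old = var_new
    lam = lam @ rot
    if kaiser:
        lam = lam * comm[:, None]
    return lam


@dataclass
class FactorModel:
    """Rotated maximum-likelihood factor solution on standardized traits."""

    loadings: pd.DataFrame          # traits x factors
    uniquenesses: pd.Series         # per trait, in [0, 1]
    variance_explained: np.ndarray  # per factor, percent of total trait variance
    scores: pd.DataFrame            # items x factors (regression method)
    heywood: bool = False

    @property
    def communalities(self) -> pd.Series:
        return 1.0 - self.uniquenesses


def fit_factors(
    traits: pd.DataFrame | np.ndarray,
    n_factors: int = 2,
    rotate: bool = True,
) -> FactorModel:
    """Extract maximum-likelihood factors from a trait table.

    Columns are standardized internally; the unrotated ML solution is
    rotated by varimax with Kaiser row normalization.  Factor scores use
    the regression (Thurstone) method, and each factor is oriented so
    that its largest-|loading| trait loads positively.
    """
    X = pd.DataFrame(traits).copy()
    if X.shape[0] <= n_factors:
        raise ValueError("need more observations than factors")
    col_names = [str(c) for c in X.columns]
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if (sd == 0).any():
        bad = [c for c, s in zip(col_names, sd) if s == 0]
        raise ValueError(f"constant trait column(s): {bad}")
    Z = (X - mu) / sd

    fa = FactorAnalysis(n_components=n_factors, svd_method="lapack", tol=1e-4,
                        max_iter=20000)
    fa.fit(Z.values)
    lam = fa.components_.T  # (p, k) loadings on standardized traits
    uniq = fa.noise_variance_.copy()
    heywood = bool((uniq <= 0).any())
    if heywood:
        warnings.warn("Heywood case: uniqueness floored at 1e-3", RuntimeWarning)
        uniq = np.maximum(uniq, 1e-3)

    if rotate:
        lam = _varimax(lam, kaiser=True)

    # orient each factor so its dominant trait loads positively
    for j in range(lam.shape[1]):
        if lam[np.argmax(np.abs(lam[:, j])), j] < 0:
            lam[:, j] = -lam[:, j]

    # regression scores: F = Z R^{-1} Lambda, R the sample correlation matrix
    R = np.corrcoef(Z.values, rowvar=False)
    scores = Z.values @ np.linalg.solve(R, lam)

    var_expl = (lam ** 2).sum(axis=0) / lam.shape[0] * 100.0
    factor_names = [f"factor{j + 1}" for j in range(lam.shape[1])]
    return FactorModel(
        loadings=pd.DataFrame(lam, index=col_names, columns=factor_names),
        uniquenesses=pd.Series(np.clip(uniq, 0.0, 1.0), index=col_names),
        variance_explained=var_expl,
        scores=pd.DataFrame(scores, index=X.index, columns=factor_names),
        heywood=heywood,
    )


#: Trait blocks defining the two facial factors by loading pattern.
OUTER_TRAITS = ("face_height", "forehead_height", "top_hair", "beard", "side_hair")
INNER_TRAITS = ("eye_size", "interocular", "mouth_width", "eyes_to_mouth", "philtrum")


def label_facial_factors(model: FactorModel) -> FactorModel:
    """Relabel a 2-factor solution as outer (factor1) / inner (factor2).

    Factor extraction order and orientation are arbitrary; this assigns
    the factor with the larger summed |loading| over the inner-feature
    traits (eyes, interocular span, mouth, philtrum) to ``factor2`` and
    the other to ``factor1``, then orients factor2 so ``eyes_to_mouth``
    loads positively and factor1 so ``face_height`` loads positively.
    Only names, column order and signs change.
    """
    if model.loadings.shape[1] != 2:
        raise ValueError("labelling requires exactly 2 factors")
    L = model.loadings
    inner_mass = L.loc[list(INNER_TRAITS)].abs().sum(axis=0)
    inner_col = inner_mass.idxmax()
    outer_col = [c for c in L.columns if c != inner_col][0]
    lam = L[[outer_col, inner_col]].copy()
    scores = model.scores[[outer_col, inner_col]].copy()
    lam.columns = scores.columns = ["factor1", "factor2"]
    for col, anchor in (("factor1", "face_height"), ("factor2", "eyes_to_mouth")):
        if lam.loc[anchor, col] < 0:
            lam[col] = -lam[col]
            scores[col] = -scores[col]
    var = (lam.values ** 2).sum(axis=0) / lam.shape[0] * 100.0
    return FactorModel(
        loadings=lam,
        uniquenesses=model.uniquenesses,
        variance_explained=var,
        scores=scores,
        heywood=model.heywood,
    )


def tucker_congruence(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Tucker congruence coefficients between columns of two loading matrices."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na = np.sqrt((a ** 2).sum(axis=0))
    nb = np.sqrt((b ** 2).sum(axis=0))
    return (a.T @ b) / np.outer(na, nb)


# ---------------------------------------------------------------------------
# Ordinations
# ---------------------------------------------------------------------------

@dataclass
class CVAResult:
    """Canonical variate analysis of grouped trait data."""

    axes: np.ndarray          # (p, n_axes) trait-space directions
    eigenvalues: np.ndarray   # descending, nonnegative
    centroids: pd.DataFrame   # groups x n_axes, canonical space
    scores: pd.DataFrame      # items x n_axes
    reassigned: pd.Series     # nearest-centroid group per item
    groups: pd.Series

    @property
    def reassignment_accuracy(self) -> float:
        return float((self.reassigned.values == self.groups.values).mean())


def _scatter_matrices(X: np.ndarray, labels: np.ndarray):
    grand = X.mean(axis=0)
    W = np.zeros((X.shape[1], X.shape[1]))
    B = np.zeros_like(W)
    for g in np.unique(labels):
        Xg = X[labels == g]
        mg = Xg.mean(axis=0)
        W += (Xg - mg).T @ (Xg - mg)
        d = (mg - grand)[:, None]
        B += len(Xg) * (d @ d.T)
    return B, W


def cva(
    traits: pd.DataFrame | np.ndarray,
    groups,
    ridge: float | None = None,
) -> CVAResult:
    """Canonical variate analysis.

    Axes are eigenvectors of ``W^{-1} B`` (W = pooled within-group
    scatter with divisor n − g, B = between-group scatter), items are
    reassigned to the nearest group centroid in canonical space.  Pass
    ``ridge`` (e.g. ``1e-8``) to regularize a singular W by
    ``ridge * trace(W)/p`` on the diagonal.
    """
    X = pd.DataFrame(traits)
    labels = pd.Series(np.asarray(groups), index=X.index, name="group")
    uniq, counts = np.unique(labels.values, return_counts=True)
    if len(uniq) < 2 or (counts < 2).any():
        raise ValueError("need >= 2 groups with >= 2 items each")
    Xv = X.values.astype(float)
    n, p = Xv.shape
    g = len(uniq)
    B, W = _scatter_matrices(Xv, labels.values)
    Wp = W / (n - g)  # unbiased pooled within-group covariance
    if ridge is not None:
        Wp = Wp + ridge * np.trace(Wp) / p * np.eye(p)
    try:
        evals, evecs = scipy.linalg.eigh(B / (n - g), Wp)
    except scipy.linalg.LinAlgError as exc:
        raise SingularScatterError(
            "within-group scatter is singular; pass ridge=1e-8"
        ) from exc
    if not np.all(np.isfinite(evals)):
        raise SingularScatterError(
            "within-group scatter is singular; pass ridge=1e-8"
        )
    order = np.argsort(evals)[::-1]
    n_axes = min(g - 1, p)
    evals = np.clip(evals[order][:n_axes], 0.0, None)
    axes = evecs[:, order][:, :n_axes]

    scores = (Xv - Xv.mean(axis=0)) @ axes
    cent = pd.DataFrame(
        [scores[labels.values == grp].mean(axis=0) for grp in uniq],
        index=pd.Index(uniq, name="group"),
        columns=[f"cv{j + 1}" for j in range(n_axes)],
    )
    d2 = ((scores[:, None, :] - cent.values[None, :, :]) ** 2).sum(axis=2)
    reassigned = pd.Series(uniq[np.argmin(d2, axis=1)], index=X.index, name="reassigned")
    return CVAResult(
        axes=axes,
        eigenvalues=evals,
        centroids=cent,
        scores=pd.DataFrame(scores, index=X.index, columns=cent.columns),
        reassigned=reassigned,
        groups=labels,
    )


def cva_loo_accuracy(traits: pd.DataFrame | np.ndarray, groups,
                     ridge: float | None = None) -> float:
    """Leave-one-out reassignment accuracy of the CVA nearest-centroid rule."""
    X = pd.DataFrame(traits).reset_index(drop=True)
    labels = np.asarray(groups)
    hits = 0
    for i in range(len(X)):
        keep = np.ones(len(X), dtype=bool)
        keep[i] = False
        res = cva(X.loc[keep], labels[keep], ridge=ridge)
        sc = (X.iloc[i].values - X.loc[keep].values.mean(axis=0)) @ res.axes
        d2 = ((res.centroids.values - sc) ** 2).sum(axis=1)
        if res.centroids.index[int(np.argmin(d2))] == labels[i]:
            hits += 1
    return hits / len(X)


def pca(matrix: pd.DataFrame | np.ndarray, standardize: bool = True):
    """Centered (optionally standardized) PCA via SVD.

    Returns ``(scores, loadings, variance_fractions)``; fractions sum to 1.
    """
    X = np.asarray(pd.DataFrame(matrix).values, dtype=float)
    n, p = X.shape
    if n < 2 or p < 2:
        raise ValueError("need >= 2 items and >= 2 variables")
    Xc = X - X.mean(axis=0)
    if standardize:
        sd = X.std(axis=0, ddof=1)
        if (sd == 0).all():
            raise ValueError("degenerate input: all variables constant")
        sd = np.where(sd == 0, 1.0, sd)
        Xc = Xc / sd
    if np.allclose(Xc, 0):
        raise ValueError("degenerate input: constant matrix")
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    scores = u * s
    var = s ** 2
    return scores, vt.T, var / var.sum()


# ---------------------------------------------------------------------------
# Landmark file IO
# ---------------------------------------------------------------------------

def load_landmarks(path: str | Path, format: str | None = None) -> dict[str, LandmarkSet]:
    """Read landmark sets from a TPS or CSV file.

    TPS coordinates use a bottom-left origin and are negated in y on
    read; internal coordinates are always top-left-origin.  CSV files
    must have columns ``image_id, point_name, x, y``.
    """
    path = Path(path)
    if format is None:
        format = "tps" if path.suffix.lower() == ".tps" else "csv"
    if format == "tps":
        return _load_tps(path)
    if format == "csv":
        return _load_csv(path)
    raise ValueError("format must be 'tps' or 'csv'")


def _load_tps(path: Path) -> dict[str, LandmarkSet]:
    out: dict[str, LandmarkSet] = {}
    lines = Path(path).read_text().splitlines()
    i, record = 0, 0
    while i < len(lines):
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if not line.upper().startswith("LM="):
            raise ValueError(f"{path}: expected 'LM=' at line {i + 1}")
        record += 1
        n_pts = int(line.split("=", 1)[1])
        if n_pts != 19:
            raise ValueError(
                f"{path}, record {record}: expected LM=19, got LM={n_pts}"
            )
        coords = []
        for j in range(n_pts):
            x, y = lines[i + 1 + j].split()
            coords.append((float(x), -float(y)))  # flip to top-left origin
        i += 1 + n_pts
        image_id = f"record_{record}"
        while i < len(lines) and lines[i].strip() and "=" in lines[i] \
                and not lines[i].strip().upper().startswith("LM="):
            key, val = lines[i].strip().split("=", 1)
            if key.upper() in ("ID", "IMAGE"):
                image_id = val.strip()
            i += 1
        out[image_id] = LandmarkSet.from_array(np.array(coords))
    return out


def _load_csv(path: Path) -> dict[str, LandmarkSet]:
    df = pd.read_csv(path)
    required = {"image_id", "point_name", "x", "y"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: CSV needs columns {sorted(required)}")
    out: dict[str, LandmarkSet] = {}
    for image_id, sub in df.groupby("image_id", sort=False):
        if len(sub) != 19:
            raise ValueError(
                f"{path}, image {image_id!r}: expected 19 landmarks, got {len(sub)}"
            )
        pts = {r.point_name: (float(r.x), float(r.y)) for r in sub.itertuples()}
        out[str(image_id)] = LandmarkSet(pts)
    return out


def save_landmarks_tps(landmarks: dict[str, LandmarkSet], path: str | Path) -> None:
    """Write TPS records (y negated back to the bottom-left convention)."""
    chunks = []
    for image_id, lm in landmarks.items():
        coords = lm.as_array()
        body = "\n".join(f"{x:.6f} {-y:.6f}" for x, y in coords)
        chunks.append(f"LM=19\n{body}\nID={image_id}\n")
    Path(path).write_text("\n".join(chunks))


def save_landmarks_csv(landmarks: dict[str, LandmarkSet], path: str | Path) -> None:
    rows = [
        {"image_id": image_id, "point_name": name, "x": lm[name][0], "y": lm[name][1]}
        for image_id, lm in landmarks.items()
        for name in LANDMARK_NAMES
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
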
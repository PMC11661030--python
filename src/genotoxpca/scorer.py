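"""Fixed-coefficient genotoxicity scoring, cutoff derivation and zoning.

The published four-gene projection lets a user score a new compound's mean
log2(exp/cont) profile without refitting anything:

    Y1 = -0.501 (xBax-0.320)/0.790 - 0.500 (xBtg2-0.262)/0.946
         - 0.516 (xCcng1-0.562)/1.166 - 0.483 (xCdkn1a-0.402)/1.352

All four PC1 coefficients are negative, so coordinate induction of the
markers drives Y1 down: strongly negative PC1 is the genotoxic signature.

Two PC1 decision values are carried side by side and must not be conflated:

* ``PUBLISHED_CUTOFF`` (-0.507), the literal printed decision value;
* the *derived* cutoff, the midpoint between the most positive PC1 among
  labeled genotoxic points and the most negative PC1 among labeled
  non-genotoxic points. Applied to the printed extreme scores (-1.168 and
  -0.778) the midpoint rule yields -0.973, not -0.507; the published
  number cannot be reproduced from its stated inputs, so it is stored as a
  constant and never recomputed.
"""
from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .errors import DomainError
from .pca import StandardizedPCA, _as_frame
from .types import (
    ChemClass,
    NON_GENOTOXIC_CLASSES,
    ScoreResult,
    Zone,
    ZoneBoundaries,
)

#: Printed decision value, kept verbatim; see module docstring.
PUBLISHED_CUTOFF = -0.507


def published_model() -> StandardizedPCA:
    """The published four-gene projection as a ready-to-use model."""
    with resources.files("genotoxpca.data").joinpath("published_model.tsv").open(
        "r"
    ) as fh:
        table = pd.read_csv(fh, sep="\t", comment="#")
    return StandardizedPCA.from_constants(
        feature_names=table["gene"],
        mu=table["mu"],
        sigma=table["sigma"],
        components=np.vstack([table["pc1_loading"], table["pc2_loading"]]),
    )


def score_compound(profile, model: StandardizedPCA | None = None) -> ScoreResult:
    """Score one mean log2-ratio profile with the (published) projection.

    *profile* may be a mapping/Series of gene -> ratio or a 1-row frame.
    """
    model = model if model is not None else published_model()
    if isinstance(profile, dict):
        profile = pd.Series(profile)
    if isinstance(profile, pd.Series):
        missing = [g for g in model.feature_names_in_ if g not in profile.index]
        if missing:
            raise DomainError(f"profile missing gene(s): {missing}")
        frame = profile.to_frame().T
        row_id = str(profile.name) if profile.name is not None else "profile"
    else:
        frame = _as_frame(profile)
        if len(frame) != 1:
            raise DomainError("score_compound expects a single profile row")
        row_id = str(frame.index[0])
    scores = model.score_frame(frame)
    pc2 = float(scores.iloc[0, 1]) if scores.shape[1] > 1 else 0.0
    return ScoreResult(row=row_id, pc1=float(scores.iloc[0, 0]), pc2=pc2)


def _split_by_class(scores: pd.DataFrame, labels: pd.Series):
    labels = labels.map(lambda v: ChemClass(v))
    labels = labels.reindex(scores.index)
    if labels.isna().any():
        missing = labels[labels.isna()].index.tolist()
        raise DomainError(f"no class label for dose point(s): {missing}")
    gthc = scores.loc[labels[labels == ChemClass.GTHC].index]
    nongtx = scores.loc[labels[labels.isin(NON_GENOTOXIC_CLASSES)].index]
    if gthc.empty:
        raise DomainError("no GTHC-labeled scores: cannot derive a cutoff")
    if nongtx.empty:
        raise DomainError("no NGTHC/NGTNHC-labeled scores: cannot derive a cutoff")
    return gthc, nongtx


def zone_boundaries(scores: pd.DataFrame, labels: pd.Series) -> ZoneBoundaries:
    """PC1 zone boundaries from labeled reference scores.

    Intermediate-labeled points are ignored: they are the query set the
    zones exist to interrogate.
    """
    gthc, nongtx = _split_by_class(scores, labels)
    g_idx = gthc["pc1"].idxmax()
    n_idx = nongtx["pc1"].idxmin()
    return ZoneBoundaries(
        gthc_max_pc1=float(gthc.loc[g_idx, "pc1"]),
        nongtx_min_pc1=float(nongtx.loc[n_idx, "pc1"]),
        gthc_argmax=str(g_idx),
        nongtx_argmin=str(n_idx),
    )


def derive_cutoff(scores: pd.DataFrame, labels: pd.Series) -> ZoneBoundaries:
    """Midpoint cutoff between the extreme labeled points of the two classes.

    Returns the full :class:`ZoneBoundaries` record; its ``cutoff`` property
    is the midpoint and the two extreme points' identifiers are attached.
    """
    return zone_boundaries(scores, labels)


def classify_zone(score, boundaries: ZoneBoundaries) -> Zone:
    """Assign a PC1 score (or :class:`ScoreResult`) to one of three zones.

    Boundary values belong to the adjacent non-intermediate zone: the
    extreme reference points sit inside their own class areas.
    """
    if boundaries.gthc_max_pc1 > boundaries.nongtx_min_pc1:
        raise DomainError(
            "inverted boundaries: GTHC maximum exceeds non-genotoxic minimum"
        )
    pc1 = score.pc1 if isinstance(score, ScoreResult) else float(score)
    if pc1 <= boundaries.gthc_max_pc1:
        return Zone.GTHC_ZONE
    if pc1 >= boundaries.nongtx_min_pc1:
        return Zone.NON_GENOTOXIC_ZONE
    return Zone.INTERMEDIATE_ZONE


def classify_scores(scores: pd.DataFrame, boundaries: ZoneBoundaries) -> pd.Series:
    """Vectorized three-zone assignment for a score frame."""
    return pd.Series(
        [classify_zone(v, boundaries) for v in scores["pc1"]],
        index=scores.index,
        name="zone",
    )


class GenotoxZoneClassifier(ClassifierMixin, BaseEstimator):
    """Three-zone PC1 classifier over a ratio matrix.

    ``fit(X, y)`` takes a dose-point x gene ratio frame and per-row class
    labels (GTHC / NGTHC / NGTNHC / INTERMEDIATE). Unless a prefit
    ``pca`` is supplied, a :class:`StandardizedPCA` is fitted on ``X`` and
    oriented by the GTHC labels; zone boundaries are then derived from the
    labeled typical points. ``predict`` assigns zones to new profiles.

    Attributes
    ----------
    pca_ : StandardizedPCA
    boundaries_ : ZoneBoundaries
    cutoff_ : float
        Midpoint cutoff derived from the training labels.
    """

    def __init__(self, pca: StandardizedPCA | str = "fit"):
        self.pca = pca

    def fit(self, X, y) -> "GenotoxZoneClassifier":
        df = _as_frame(X)
        labels = pd.Series(list(y), index=df.index) if not isinstance(
            y, pd.Series
        ) else y.reindex(df.index)
        if self.pca == "published":
            self.pca_ = published_model()
        elif self.pca == "fit":
            self.pca_ = StandardizedPCA(orient="labels").fit(df, y=labels)
        elif isinstance(self.pca, StandardizedPCA):
            self.pca_ = self.pca
        else:
            raise DomainError(f"invalid pca argument: {self.pca!r}")
        scores = self.pca_.score_frame(df)
        self.boundaries_ = zone_boundaries(scores, labels)
        self.cutoff_ = self.boundaries_.cutoff
        self.classes_ = np.asarray([z.value for z in Zone], dtype=object)
        return self

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "boundaries_")
        return self.pca_.score_frame(_as_frame(X))["pc1"].to_numpy()

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "boundaries_")
        pc1 = self.decision_function(X)
        return np.asarray(
            [classify_zone(v, self.boundaries_).value for v in pc1], dtype=object
        )
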
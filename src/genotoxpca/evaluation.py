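"""Separation accuracy and the add-your-data augmentation workflow."""
from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import DomainError
from .pca import StandardizedPCA, _as_frame
from .scorer import derive_cutoff
from .types import ChemClass, NON_GENOTOXIC_CLASSES


@dataclass
class SeparationReport:
    """How well PC1 separates labeled genotoxic from non-genotoxic points.

    ``separable`` means the two labeled sets do not overlap on PC1 at all
    (max GTHC < min non-genotoxic); in that case the midpoint cutoff
    classifies every labeled point correctly and ``accuracy`` is 1.
    Points sitting exactly on the cutoff count as misclassified.
    """

    n_points: int
    n_gthc: int
    n_nongtx: int
    separable: bool
    accuracy: float
    cutoff: float
    gthc_max_pc1: float
    nongtx_min_pc1: float
    misclassified: list[str] = field(default_factory=list)
    n_intermediate: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])

    def to_text(self) -> str:
        lines = [
            f"labeled points: {self.n_points} "
            f"({self.n_gthc} GTHC, {self.n_nongtx} NGTHC+NGTNHC; "
            f"{self.n_intermediate} intermediate excluded)",
            f"PC1 extremes: GTHC max {self.gthc_max_pc1:.3f}, "
            f"non-genotoxic min {self.nongtx_min_pc1:.3f}",
            f"derived cutoff (midpoint): {self.cutoff:.3f}",
            f"separable: {self.separable}",
            f"accuracy at derived cutoff: {self.accuracy:.3f}",
        ]
        if self.misclassified:
            lines.append("misclassified: " + ", ".join(self.misclassified))
        return "\n".join(lines)


def separation_accuracy(scores: pd.DataFrame, labels: pd.Series) -> SeparationReport:
    """Score the PC1 separation of labeled reference points.

    GTHC points must fall strictly below the derived midpoint cutoff and
    NGTHC/NGTNHC points strictly above it; intermediates are excluded from
    both the cutoff and the accuracy, and only counted.
    """
    labels = pd.Series(labels).map(lambda v: ChemClass(v))
    labels = labels.reindex(scores.index)
    boundaries = derive_cutoff(scores, labels)
    cutoff = boundaries.cutoff

    gthc_idx = labels[labels == ChemClass.GTHC].index
    nongtx_idx = labels[labels.isin(NON_GENOTOXIC_CLASSES)].index
    inter_idx = labels[labels == ChemClass.INTERMEDIATE].index

    pc1 = scores["pc1"]
    correct_gthc = pc1.loc[gthc_idx] < cutoff
    correct_nongtx = pc1.loc[nongtx_idx] > cutoff
    miss = list(correct_gthc[~correct_gthc].index) + list(
        correct_nongtx[~correct_nongtx].index
    )
    n_points = len(gthc_idx) + len(nongtx_idx)
    accuracy = (int(correct_gthc.sum()) + int(correct_nongtx.sum())) / n_points
    return SeparationReport(
        n_points=n_points,
        n_gthc=len(gthc_idx),
        n_nongtx=len(nongtx_idx),
        separable=boundaries.separated,
        accuracy=accuracy,
        cutoff=cutoff,
        gthc_max_pc1=boundaries.gthc_max_pc1,
        nongtx_min_pc1=boundaries.nongtx_min_pc1,
        misclassified=[str(m) for m in miss],
        n_intermediate=len(inter_idx),
    )


@dataclass
class AugmentResult:
    """Outcome of refitting the PCA after appending user rows."""

    model: StandardizedPCA
    scores_before: pd.DataFrame
    scores_after: pd.DataFrame
    pc1_delta: pd.Series
    max_abs_delta: float


def augment_and_rescore(
    base, base_labels: pd.Series, new_rows
) -> AugmentResult:
    """Append new dose points to a reference matrix and re-run the PCA.

    Both the standardization constants and the eigenvectors are refit on
    the union, then re-oriented by the base GTHC labels; the result pairs
    each base row's PC1 before and after augmentation, quantifying how
    stable the reference chart is under the user's additions.
    """
    base_df = _as_frame(base)
    new_df = _as_frame(new_rows) if new_rows is not None else pd.DataFrame(
        columns=base_df.columns
    )
    if len(new_df) and list(new_df.columns) != list(base_df.columns):
        if set(new_df.columns) != set(base_df.columns):
            raise DomainError("augmentation rows use a different gene panel")
        new_df = new_df.loc[:, base_df.columns]
    overlap = set(base_df.index) & set(new_df.index)
    if overlap:
        raise DomainError(f"augmentation rows duplicate base ids: {sorted(overlap)}")

    base_labels = pd.Series(base_labels).reindex(base_df.index)

    before_model = StandardizedPCA(orient="labels").fit(base_df, y=base_labels)
    scores_before = before_model.score_frame(base_df)

    if len(new_df):
        union = pd.concat([base_df, new_df], axis=0)
        union_labels = pd.concat(
            [base_labels, pd.Series([None] * len(new_df), index=new_df.index)]
        )
    else:
        union = base_df
        union_labels = base_labels
    after_model = StandardizedPCA(orient="labels").fit(
        union, y=union_labels.map(lambda v: v if v is not None else ChemClass.INTERMEDIATE)
    )
    scores_after = after_model.score_frame(union)

    delta = scores_after.loc[base_df.index, "pc1"] - scores_before["pc1"]
    return AugmentResult(
        model=after_model,
        scores_before=scores_before,
        scores_after=scores_after,
        pc1_delta=delta,
        max_abs_delta=float(delta.abs().max()) if len(delta) else 0.0,
    )
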
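"""Multiangle view aggregation, trait correlations, and the GWAS
suggestive-threshold utility.

Each plant is photographed in fixed angular steps on a turntable (15°
steps → 24 views) with several biological replicates. Views of one
accession are aggregated by the plain mean and population standard
deviation over all (replicate, angle) vectors — replicates are not
nested, every view counts once. Trait-trait relationships across the
panel use Pearson's correlation on accession-level means.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from rootscape.errors import ParameterError, StatisticsError, ValidationError
from rootscape.descriptors import TraitRegistry, TraitVector
from rootscape.image_io import TraitTable

logger = logging.getLogger(__name__)


def expected_view_count(step_deg: int) -> int:
    """Number of views for a full turn at the given angular step (15° → 24)."""
    if not 1 <= step_deg <= 360 or 360 % step_deg != 0:
        raise ParameterError(f"angular step must divide 360, got {step_deg}")
    return 360 // step_deg


def suggestive_threshold(n_tests: int) -> float:
    """Suggestive GWAS P-value threshold 1/n for n effective independent tests."""
    if n_tests < 1:
        raise ParameterError(f"n_tests must be >= 1, got {n_tests}")
    return 1.0 / n_tests


@dataclass
class ViewSet:
    """Trait vectors of one (accession, replicate) across turntable angles."""

    accession_id: str
    replicate: int
    entries: dict[int, TraitVector] = field(default_factory=dict)
    step_deg: int = 15

    def __post_init__(self) -> None:
        for angle in self.entries:
            if angle % self.step_deg != 0:
                raise ValidationError(
                    f"angle {angle} is not a multiple of the {self.step_deg}° step"
                )
        if len(self.entries) > expected_view_count(self.step_deg):
            raise ValidationError("more views than the angular step permits")

    @property
    def registry(self) -> TraitRegistry | None:
        for v in self.entries.values():
            return v.registry
        return None

    def missing_angles(self) -> list[int]:
        return [
            a for a in range(0, 360, self.step_deg) if a not in self.entries
        ]


@dataclass(frozen=True)
class AccessionSummary:
    """Per-channel mean/sd over all views of one accession."""

    accession_id: str
    mean: np.ndarray
    sd: np.ndarray
    n_views: int
    registry: TraitRegistry


def aggregate_accession(views: list[ViewSet]) -> AccessionSummary:
    """Collapse all (replicate, angle) vectors of one accession.

    Arithmetic mean and population (n-denominator) standard deviation per
    channel. A replicate with fewer than the expected number of angles is
    used as-is with a logged warning naming the missing angles.
    """
    if not views:
        raise ValidationError("no views to aggregate")
    accession = views[0].accession_id
    registry = None
    vectors = []
    for vs in views:
        if vs.accession_id != accession:
            raise ValidationError(
                f"mixed accessions: {vs.accession_id!r} vs {accession!r}"
            )
        missing = vs.missing_angles()
        if missing and vs.entries:
            logger.warning(
                "accession %s replicate %d is missing angles %s",
                accession, vs.replicate, missing,
            )
        for angle in sorted(vs.entries):
            vec = vs.entries[angle]
            if registry is None:
                registry = vec.registry
            elif vec.registry is not registry and vec.registry != registry:
                raise ValidationError("views mix different trait registries")
            vectors.append(vec.values)
    if not vectors:
        raise ValidationError("no trait vectors in the given view sets")
    stacked = np.vstack(vectors)
    return AccessionSummary(
        accession_id=accession,
        mean=stacked.mean(axis=0),
        sd=stacked.std(axis=0),  # population sd; r is denominator-invariant
        n_views=stacked.shape[0],
        registry=registry,
    )


def accession_means_frame(table: TraitTable) -> pd.DataFrame:
    """Accession-level channel means from a per-view trait table."""
    df = table.to_frame()
    return df.drop(columns=["replicate", "angle"]).groupby("accession").mean()


def pearson_correlation_matrix(table: TraitTable) -> pd.DataFrame:
    """Pairwise Pearson r between trait channels over accession means.

    Requires at least 3 accessions. Constant channels have undefined
    correlations; those entries are NaN and a warning is logged. The
    diagonal is exactly 1 for non-constant channels.
    """
    means = accession_means_frame(table)
    if means.shape[0] < 3:
        raise StatisticsError(
            f"need >= 3 accessions for correlations, got {means.shape[0]}"
        )
    constant = means.columns[means.std(axis=0) == 0].tolist()
    if constant:
        logger.warning(
            "constant channels have undefined correlations: %s%s",
            constant[:8], "..." if len(constant) > 8 else "",
        )
    corr = means.corr(method="pearson")
    np.fill_diagonal(corr.values, [np.nan if c in constant else 1.0 for c in corr.columns])
    return corr


def correlation_long_format(corr: pd.DataFrame) -> pd.DataFrame:
    """Long-format (channel_a, channel_b, r) view of a correlation matrix."""
    long = corr.stack(future_stack=True).reset_index()
    long.columns = ["channel_a", "channel_b", "r"]
    return long
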
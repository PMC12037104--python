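"""Confounding-factor nomination from drift positions.

A covariate that the classifier never saw (age, BMI, or another metabolite)
is a confounding candidate when detector events concentrate at a particular
region of its range once the error stream is ordered by it. This module
associates events with covariate values, ranks candidate covariates by how
tightly their events cluster, derives a candidate threshold from the
association, and — for the pipeline's refined estimate — locates the onset
of an error-rate increase by a maximum-likelihood two-rate split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from metadrift.data import ClinicalTable, ValidationError
from metadrift.drift import DriftEvent, ErrorStream

THRESHOLD_RULES = ("mean_of_warnings", "mean_of_drifts", "midpoint")


@dataclass
class CovariateAssociation:
    """Covariate values observed at warning and drift positions."""

    covariate: str
    values_at_warnings: list[float] = field(default_factory=list)
    values_at_drifts: list[float] = field(default_factory=list)
    threshold_rule: str = "mean_of_warnings"

    def summary(self) -> dict[str, dict[str, float]]:
        out = {}
        for level, vals in (
            ("warning", self.values_at_warnings),
            ("drift", self.values_at_drifts),
        ):
            if vals:
                out[level] = dict(
                    n=len(vals),
                    mean=float(np.mean(vals)),
                    min=float(np.min(vals)),
                    max=float(np.max(vals)),
                )
            else:
                out[level] = dict(n=0)
        return out

    @property
    def candidate_threshold(self) -> float | None:
        try:
            return derive_threshold(self, self.threshold_rule)
        except ValidationError:
            return None

    @property
    def tightness(self) -> float:
        """Range of warning values; smaller = more concentrated = stronger."""
        if not self.values_at_warnings:
            return float("inf")
        return float(np.max(self.values_at_warnings) - np.min(self.values_at_warnings))


def associate_covariate(
    events: list[DriftEvent],
    stream: ErrorStream,
    clinical: ClinicalTable,
    covariate: str,
) -> CovariateAssociation:
    """Record the covariate value of the ordered sample at each event index.

    Works identically when the "covariate" is a metabolite column copied into
    the clinical table (e.g. scanning creatinine as a candidate confounder).
    An empty event list yields an empty association (threshold undefined),
    not an error.
    """
    values = clinical.covariate(covariate)
    assoc = CovariateAssociation(covariate)
    for ev in events:
        if not 0 <= ev.index < len(stream):
            raise ValidationError(f"event index {ev.index} outside stream of length {len(stream)}")
        sid = stream.sample_ids[ev.index]
        value = float(values.loc[sid])
        if ev.level == "warning":
            assoc.values_at_warnings.append(value)
        else:
            assoc.values_at_drifts.append(value)
    return assoc


def derive_threshold(assoc: CovariateAssociation, rule: str = "mean_of_warnings") -> float:
    """Candidate confounding threshold from an association.

    ``mean_of_warnings`` / ``mean_of_drifts`` average the covariate values at
    the corresponding level; ``midpoint`` takes (min+max)/2 over both levels
    pooled.
    """
    if rule not in THRESHOLD_RULES:
        raise ValidationError(f"unknown threshold rule {rule!r}; choose from {THRESHOLD_RULES}")
    if rule == "mean_of_warnings":
        vals = assoc.values_at_warnings
        fallback = "mean_of_drifts or midpoint"
    elif rule == "mean_of_drifts":
        vals = assoc.values_at_drifts
        fallback = "mean_of_warnings or midpoint"
    else:
        vals = assoc.values_at_warnings + assoc.values_at_drifts
        fallback = "a rule with events present"
    if not vals:
        raise ValidationError(
            f"no events at the level required by {rule!r}; try {fallback}"
        )
    if rule == "midpoint":
        return float((np.min(vals) + np.max(vals)) / 2.0)
    return float(np.mean(vals))


def rank_covariates(
    associations: list[CovariateAssociation],
) -> list[CovariateAssociation]:
    """Order candidate covariates, strongest (tightest warning cluster) first."""
    return sorted(associations, key=lambda a: a.tightness)


def estimate_change_index(errors: np.ndarray) -> int | None:
    """Maximum-likelihood onset of an error-rate increase in a binary stream.

    Scans every split of the stream into a prefix and a suffix modeled as
    independent Bernoulli segments, and returns the split index maximizing
    the joint log-likelihood, restricted to splits where the suffix rate
    exceeds the prefix rate (an *increase*, the direction that degrades a
    classifier). Returns None when no such split exists. The returned index
    is the first position of the changed segment.

    This is the classical two-segment changepoint estimate; the detector
    (DDM/EDDM) answers *whether* drift occurred, and this estimate answers
    *where*, free of detection latency.
    """
    errors = np.asarray(errors, dtype=float)
    n = len(errors)
    if n < 4:
        return None
    cum = np.concatenate([[0.0], np.cumsum(errors)])
    m = np.arange(2, n - 1)  # prefix [0, m), suffix [m, n)
    k1 = cum[m]
    n1 = m.astype(float)
    k2 = cum[n] - cum[m]
    n2 = n - n1
    p1 = k1 / n1
    p2 = k2 / n2

    def loglik(k, size, p):
        out = np.zeros_like(p)
        interior = (p > 0) & (p < 1)
        out[interior] = k[interior] * np.log(p[interior]) + (
            size[interior] - k[interior]
        ) * np.log1p(-p[interior])
        return out

    total = loglik(k1, n1, p1) + loglik(k2, n2, p2)
    total[p2 <= p1] = -np.inf
    if not np.isfinite(total).any():
        return None
    return int(m[np.argmax(total)])


def plot_association(
    stream: ErrorStream,
    clinical: ClinicalTable,
    covariate: str,
    events: list[DriftEvent],
    path=None,
    concentration_track: str | None = None,
):
    """Covariate strip with event markers; optional grey-scale metabolite track.

    Returns the matplotlib figure; saves it when ``path`` is given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    values = clinical.covariate(covariate).loc[stream.sample_ids].to_numpy(dtype=float)
    x = np.arange(len(stream))
    nrows = 2 if concentration_track else 1
    fig, axes = plt.subplots(nrows, 1, figsize=(9, 2.5 * nrows), sharex=True, squeeze=False)
    ax = axes[0][0]
    ax.plot(x, values, color="0.4", lw=1)
    for ev in events:
        color = "orange" if ev.level == "warning" else "red"
        ax.axvline(ev.index, color=color, alpha=0.7, lw=1.2)
    ax.set_ylabel(covariate)
    ax.set_title(f"{covariate} along the ordered stream (orange=warning, red=drift)")
    if concentration_track:
        conc = clinical.covariate(concentration_track).loc[stream.sample_ids]
        ax2 = axes[1][0]
        ax2.imshow(
            conc.to_numpy(dtype=float)[None, :], aspect="auto", cmap="Greys",
            extent=(0, len(stream), 0, 1),
        )
        ax2.set_yticks([])
        ax2.set_ylabel(concentration_track)
    axes[-1][0].set_xlabel(f"stream position (ordered by {stream.ordering_key})")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
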
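"""Synthetic study cohorts with known ground truth for the statistics suites.

Two generators mirror the two arms of a sedation/repeatability study
design:

* :func:`generate_repeatability_table` draws a balanced goat x scan x
  cycle table from the crossed random-effects model

      y_ijk = mu + g_i + t_j + (gt)_ij + eps_ijk,

  all components Gaussian, so the intraclass correlation implied by the
  chosen variance components, sigma_g^2 / (sigma_g^2 + sigma_t^2 +
  sigma_gt^2 + sigma_eps^2), is known exactly.

* :func:`generate_paired_table` constructs baseline/post pairs with an
  exactly controlled number of discordant animals (those moving against
  the majority direction) and, optionally, exact rank placement of the
  discordant absolute differences — the structure that determines an
  exact Wilcoxon signed-rank p-value and rank-biserial effect size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cmm_io import PairedTable, StudyTable, ValidationError

__all__ = ["RepeatDesign", "PairedDesign",
           "generate_repeatability_table", "generate_paired_table"]


@dataclass(frozen=True)
class RepeatDesign:
    """Balanced crossed random-effects design for repeatability data."""

    n_goats: int = 8
    n_scans: int = 2
    n_cycles: int = 4
    grand_mean: float = 2.02
    sd_goat: float = 0.0
    sd_scan: float = 0.0
    sd_interaction: float = 0.0
    sd_cycle: float = 0.0
    seed: int = 0
    variable: str = "total_ivpd"

    def __post_init__(self) -> None:
        if min(self.n_goats, self.n_scans, self.n_cycles) < 1:
            raise ValidationError("design counts must be >= 1")
        if min(self.sd_goat, self.sd_scan, self.sd_interaction, self.sd_cycle) < 0:
            raise ValidationError("standard deviations must be >= 0")

    @property
    def true_icc(self) -> float:
        """ICC implied by the variance components (NaN if all are zero)."""
        tot = (self.sd_goat ** 2 + self.sd_scan ** 2
               + self.sd_interaction ** 2 + self.sd_cycle ** 2)
        if tot == 0:
            return float("nan")
        return self.sd_goat ** 2 / tot


def generate_repeatability_table(d: RepeatDesign) -> StudyTable:
    """Draw one balanced table from the crossed random-effects model."""
    rng = np.random.default_rng(d.seed)
    g = rng.normal(0, d.sd_goat, d.n_goats)
    t = rng.normal(0, d.sd_scan, d.n_scans)
    gt = rng.normal(0, d.sd_interaction, (d.n_goats, d.n_scans))
    eps = rng.normal(0, d.sd_cycle, (d.n_goats, d.n_scans, d.n_cycles))
    y = d.grand_mean + g[:, None, None] + t[None, :, None] + gt[:, :, None] + eps
    scan_ids = [chr(ord("A") + j) for j in range(d.n_scans)]
    records = [
        {"goat_id": f"goat{i + 1}", "scan_id": scan_ids[j],
         "cycle_index": k + 1, "variable": d.variable, "value": y[i, j, k]}
        for i in range(d.n_goats)
        for j in range(d.n_scans)
        for k in range(d.n_cycles)
    ]
    return StudyTable(pd.DataFrame.from_records(records))


@dataclass(frozen=True)
class PairedDesign:
    """Paired baseline/post design with controlled discordance structure.

    ``effect_ratio`` multiplies each goat's baseline to give its typical
    post value (< 1: the majority of goats decrease).  ``n_discordant``
    goats are forced to move in the opposite direction.  If
    ``discordant_ranks`` is given (1 = smallest absolute difference), the
    discordant differences occupy exactly those ranks.
    """

    n_goats: int = 8
    baseline_median: float = 3.28
    baseline_spread: float = 0.6
    effect_ratio: float = 0.7
    jitter: float = 0.25          # relative sd of per-goat effect jitter
    n_discordant: int = 0
    discordant_ranks: tuple[int, ...] | None = None
    allow_ties: bool = False
    seed: int = 0
    variable: str = "total_ivpd"

    def __post_init__(self) -> None:
        if self.n_goats < 1:
            raise ValidationError("n_goats must be >= 1")
        if not (0 <= self.n_discordant <= self.n_goats):
            raise ValidationError("need 0 <= n_discordant <= n_goats")
        if self.discordant_ranks is not None:
            rr = self.discordant_ranks
            if len(rr) != self.n_discordant:
                raise ValidationError("discordant_ranks length must equal n_discordant")
            if len(set(rr)) != len(rr) or any(not 1 <= r <= self.n_goats for r in rr):
                raise ValidationError("discordant_ranks must be distinct in 1..n_goats")
        if self.baseline_spread < 0 or self.jitter < 0:
            raise ValidationError("spreads must be >= 0")


def generate_paired_table(d: PairedDesign) -> PairedTable:
    """Construct one paired table honouring the discordance contract exactly.

    Absolute differences are drawn around |baseline x (effect_ratio - 1)|
    with multiplicative jitter and re-drawn until distinct (unless
    ``allow_ties``); the majority sign is that of ``effect_ratio - 1``,
    flipped for the goats whose |difference| ranks are designated
    discordant.
    """
    rng = np.random.default_rng(d.seed)
    n = d.n_goats
    baseline = d.baseline_median + d.baseline_spread * rng.standard_normal(n)
    baseline = np.abs(baseline) + 0.1 * d.baseline_median  # keep physiologic (positive)
    scale = abs(d.effect_ratio - 1.0) * baseline
    if np.all(scale == 0):
        scale = np.full(n, 0.1 * d.baseline_median)
    for _ in range(100):
        mags = scale * np.abs(1.0 + d.jitter * rng.standard_normal(n))
        mags = np.maximum(mags, 1e-9)
        if d.allow_ties or len(np.unique(mags)) == n:
            break
    order = np.argsort(mags)            # order[r-1] = goat index holding rank r
    if d.discordant_ranks is not None:
        disc_idx = order[[r - 1 for r in d.discordant_ranks]]
    else:
        disc_idx = rng.choice(n, size=d.n_discordant, replace=False)
    majority = -1.0 if d.effect_ratio < 1.0 else 1.0
    signs = np.full(n, majority)
    signs[disc_idx] = -majority
    post = baseline + signs * mags
    records = []
    for i in range(n):
        records.append({"goat_id": f"goat{i + 1}", "condition": "baseline",
                        "variable": d.variable, "value": baseline[i]})
        records.append({"goat_id": f"goat{i + 1}", "condition": "post",
                        "variable": d.variable, "value": post[i]})
    return PairedTable(pd.DataFrame.from_records(records))
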
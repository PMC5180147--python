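"""Shareholder Quorum Subsampling (coverage-standardized richness).

Classical rarefaction standardizes by the *number* of items drawn; SQS
standardizes by *coverage* — the summed relative frequency of the taxa
encountered — so that each cell is subsampled down to an equal fraction of
its underlying frequency distribution (the "quorum" q).  Per trial the
drawing units (single occurrences, or whole collections) are shuffled and
drawn in sequence; when a genus is seen for the first time its estimated
share of the true frequency distribution is added to the running coverage,
and drawing stops once the quorum is met.  The subsampled richness estimate
is the mean count of distinct genera over trials.

Sample coverage is estimated by Good's u = 1 - n1/O (n1 = genera with a
single occurrence, or known from a single publication under the
``by_reference`` rule).  Because observed relative frequencies n_i/O sum to
one while the sample only covers a fraction u of the true distribution, the
estimated true share of an observed genus is u * n_i / O; the default
stopping rule accumulates these corrected shares and the quorum is therefore
unattainable exactly when u < q, in which case the estimate is reported
missing.  Two alternative stopping rules are kept for comparison (see
:class:`SQSConfig`).  All subsampling is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError

COVERAGE_RULES = ("good", "deficit", "raw")


@dataclass(frozen=True)
class FrequencyTable:
    """Per-cell genus occurrence frequencies and coverage.

    ``counts`` maps genus -> occurrence count within the cell; ``n1`` is the
    singleton count under the configured rule; ``u = 1 - n1/O`` is Good's
    coverage estimate.
    """

    counts: pd.Series
    O: int
    n1: int
    u: float
    dominant: str

    def __post_init__(self) -> None:
        if int(self.counts.sum()) != self.O:
            raise ValidationError("frequency counts do not sum to O")
        if not 0.0 <= self.u <= 1.0:
            raise ValidationError(f"coverage u={self.u} outside [0, 1]")


@dataclass(frozen=True)
class SQSConfig:
    """Subsampling options.

    q:
        Quorum, the target coverage fraction in (0, 1].  0.4 is the
        conventional baseline for fossil occurrence data.
    trials:
        Monte-Carlo trials per cell.
    seed:
        RNG seed; identical (config, cell) pairs replay identically.
    unit:
        ``occurrence`` draws single occurrences; ``collection`` (default)
        draws whole collections, which respects the clustered structure of
        fossil sampling.
    exclude_dominant:
        Drop the most frequent genus's share from both the running coverage
        and the quorum target, damping the leverage of a single dominant
        taxon.  The dominant genus still counts toward richness when drawn.
    singleton_rule:
        ``by_occurrence`` counts n1 over occurrence counts;
        ``by_reference`` (default) counts genera known from a single
        publication, which corrects for monographic over-splitting.
    coverage_rule:
        ``good`` (default): accumulate Good-corrected shares u*n_i/O against
        target q (unattainable when u < q).  ``deficit``: accumulate raw
        shares against target q*u.  ``raw``: raw shares against target q.
    """

    q: float = 0.4
    trials: int = 1000
    seed: int = 0
    unit: str = "collection"
    exclude_dominant: bool = True
    singleton_rule: str = "by_reference"
    coverage_rule: str = "good"

    def __post_init__(self) -> None:
        if not 0.0 < self.q <= 1.0:
            raise ConfigurationError(f"quorum must be in (0, 1], got {self.q}")
        if self.trials < 1:
            raise ConfigurationError("trials must be >= 1")
        if self.unit not in ("occurrence", "collection"):
            raise ConfigurationError(f"unknown drawing unit {self.unit!r}")
        if self.singleton_rule not in ("by_occurrence", "by_reference"):
            raise ConfigurationError(f"unknown singleton rule {self.singleton_rule!r}")
        if self.coverage_rule not in COVERAGE_RULES:
            raise ConfigurationError(f"unknown coverage rule {self.coverage_rule!r}")


@dataclass(frozen=True)
class SQSResult:
    """Mean/sd subsampled richness for one cell; missing when u < q."""

    mean_richness: float
    sd_richness: float
    u: float
    attained: bool
    n_trials: int = 0

    @property
    def missing(self) -> bool:
        return not self.attained


def genus_frequency_table(
    occurrences: pd.DataFrame, singleton_rule: str = "by_occurrence"
) -> FrequencyTable:
    """Build the genus frequency table for one cell's occurrence rows."""
    if len(occurrences) == 0:
        raise ValidationError("empty cell")
    counts = occurrences["genus"].value_counts()
    O = int(counts.sum())
    if singleton_rule == "by_occurrence":
        n1 = int((counts == 1).sum())
    elif singleton_rule == "by_reference":
        refs = occurrences.groupby("genus")["reference_id"].nunique()
        n1 = int((refs == 1).sum())
    else:
        raise ConfigurationError(f"unknown singleton rule {singleton_rule!r}")
    u = 1.0 - n1 / O
    return FrequencyTable(counts=counts, O=O, n1=n1, u=u, dominant=str(counts.index[0]))


def _coverage_target_and_shares(
    freq: FrequencyTable, codes_counts: np.ndarray, cfg: SQSConfig, dominant_code: int
) -> tuple[float, np.ndarray]:
    """Per-genus coverage increments and the stopping target for one cell."""
    shares = codes_counts / freq.O
    p_dom = shares[dominant_code]
    scale = (1.0 - p_dom) if cfg.exclude_dominant else 1.0
    if cfg.coverage_rule == "good":
        increments = freq.u * shares
        target = cfg.q * scale
    elif cfg.coverage_rule == "deficit":
        increments = shares.copy()
        target = cfg.q * freq.u * scale
    else:  # raw
        increments = shares.copy()
        target = cfg.q * scale
    if cfg.exclude_dominant:
        increments = increments.copy()
        increments[dominant_code] = 0.0
    return target, increments


def sqs_subsample(
    occurrences: pd.DataFrame,
    cfg: SQSConfig,
    freq: FrequencyTable | None = None,
    rng: np.random.Generator | None = None,
) -> SQSResult:
    """Coverage-standardized richness for one cell of occurrence rows.

    ``occurrences`` needs columns genus, collection_id (for the collection
    unit) and reference_id (for the by_reference singleton rule).  ``freq``
    must have been built with the same singleton rule when supplied.
    """
    if freq is None:
        freq = genus_frequency_table(occurrences, cfg.singleton_rule)
    if rng is None:
        rng = np.random.default_rng(cfg.seed)

    codes, genera = pd.factorize(occurrences["genus"], sort=True)
    n_genera = len(genera)
    counts = np.bincount(codes, minlength=n_genera)
    dominant_code = int(np.argmax(counts))

    attained = freq.u >= cfg.q - 1e-12
    if not attained:
        return SQSResult(float("nan"), float("nan"), freq.u, False, 0)
    if n_genera == 1:
        return SQSResult(1.0, 0.0, freq.u, True, cfg.trials)

    target, increments = _coverage_target_and_shares(freq, counts, cfg, dominant_code)
    T = cfg.trials

    if cfg.unit == "occurrence":
        richness = _subsample_occurrence_units(codes, increments, n_genera, target, T, rng)
    else:
        coll_codes, _ = pd.factorize(occurrences["collection_id"])
        richness = _subsample_collection_units(
            codes, coll_codes, increments, n_genera, target, T, rng
        )
    return SQSResult(
        float(np.mean(richness)), float(np.std(richness, ddof=1)) if T > 1 else 0.0,
        freq.u, True, T,
    )


_EPS = 1e-9  # float-sum guard so that e.g. q=1, u=1 draws every unit exactly


def _subsample_occurrence_units(codes, increments, n_genera, target, T, rng):
    O = len(codes)
    perms = rng.permuted(np.tile(codes, (T, 1)), axis=1)
    rows = np.arange(T)
    seen = np.zeros((T, n_genera), dtype=bool)
    cov = np.zeros(T)
    ndist = np.zeros(T, dtype=np.int64)
    stopped = np.zeros(T, dtype=bool)
    richness = np.zeros(T, dtype=np.int64)
    for j in range(O):
        g = perms[:, j]
        new = ~seen[rows, g] & ~stopped
        seen[rows[new], g[new]] = True
        cov[new] += increments[g[new]]
        ndist[new] += 1
        crossed = ~stopped & (cov >= target - _EPS)
        richness[crossed] = ndist[crossed]
        stopped |= crossed
        if stopped.all():
            break
    richness[~stopped] = ndist[~stopped]  # quorum never met within the cell: full draw
    return richness


def _subsample_collection_units(codes, coll_codes, increments, n_genera, target, T, rng):
    n_coll = int(coll_codes.max()) + 1
    membership = np.zeros((n_coll, n_genera), dtype=bool)
    membership[coll_codes, codes] = True
    perms = rng.permuted(np.tile(np.arange(n_coll), (T, 1)), axis=1)
    seen = np.zeros((T, n_genera), dtype=bool)
    cov = np.zeros(T)
    stopped = np.zeros(T, dtype=bool)
    richness = np.zeros(T, dtype=np.int64)
    for j in range(n_coll):
        active = ~stopped
        if not active.any():
            break
        drawn = membership[perms[:, j]]  # (T, n_genera)
        new = drawn & ~seen & active[:, None]
        cov += new @ increments
        seen |= new
        crossed = active & (cov >= target - _EPS)
        richness[crossed] = seen[crossed].sum(axis=1)
        stopped |= crossed
    richness[~stopped] = seen[~stopped].sum(axis=1)
    return richness


def sqs_profile(
    table,
    scheme,
    cfg: SQSConfig,
    cells: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Run SQS over every (bin, band) cell of an occurrence table.

    Per-cell RNG streams are spawned deterministically from ``cfg.seed`` and
    the cell's identity, so results are replayable regardless of cell order.
    Per-cell failures are recorded in the ``error`` column, never raised.
    """
    from .cohorts import cell_keys  # deferred to avoid import cycle

    keys = cell_keys(table, scheme)
    df = table.df.assign(bin=keys["bin"], band_index=keys["band_index"])
    df = df.dropna(subset=["bin"])
    label_pos = {lab: i for i, lab in enumerate(scheme.labels)}

    rows = []
    for (bin_label, band_index), cell_df in df.groupby(["bin", "band_index"], observed=True):
        entry = {
            "bin": bin_label,
            "band_index": int(band_index),
            "G": int(cell_df["genus"].nunique()),
            "O": int(len(cell_df)),
        }
        try:
            seed_seq = np.random.SeedSequence(
                entropy=(int(cfg.seed), int(label_pos[bin_label]), int(band_index) + 6)
            )
            res = sqs_subsample(cell_df, cfg, rng=np.random.default_rng(seed_seq))
            entry.update(
                u=res.u, mean_richness=res.mean_richness, sd_richness=res.sd_richness,
                attained=res.attained, error="",
            )
        except Exception as exc:  # per-cell errors must not abort the profile
            entry.update(
                u=np.nan, mean_richness=np.nan, sd_richness=np.nan,
                attained=False, error=f"{type(exc).__name__}: {exc}",
            )
        rows.append(entry)
    out = pd.DataFrame(rows)
    out["bin"] = pd.Categorical(out["bin"], categories=scheme.labels, ordered=True)
    return out.sort_values(["bin", "band_index"]).reset_index(drop=True)
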
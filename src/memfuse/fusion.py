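"""Symmetric EEG-MEG fusion, step 1: SNR normalisation and concatenation.

EEG (volts) and MEG (tesla) live on incommensurate scales.  Dividing each
modality's data *and* lead field by the mean baseline standard deviation over
its channels makes both dimensionless with unit-scale background, so their
rows can be stacked into one joint inverse problem.  The per-channel noise
variances of the scaled baselines form the diagonal noise covariance carried
into the solvers (no pre-whitening of the data itself).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .forward import LeadField

logger = logging.getLogger(__name__)


@dataclass
class BaselineStats:
    """Per-channel baseline standard deviations and their modality mean."""

    sigma: np.ndarray    # per-channel std, unbiased (tau - 1)
    sigma_bar: float     # mean over channels
    n_channels: int


@dataclass
class FusedRecording:
    """Row-concatenated, SNR-normalised multimodal recording.

    Row blocks are ordered EEG first, then MEG; ``modalities`` holds the
    per-row modality tag so the blocks can be recovered losslessly.
    """

    data: np.ndarray          # (q_E + q_M, tau) scaled data
    gain: np.ndarray          # (q_E + q_M, p) scaled lead field
    baseline: np.ndarray      # (q_E + q_M, tau) scaled baseline
    modalities: np.ndarray    # (q_E + q_M,) str tags per row
    noise_var: np.ndarray     # diagonal of the noise covariance

    def block(self, modality: str) -> tuple[np.ndarray, np.ndarray]:
        mask = self.modalities == modality
        return self.data[mask], self.gain[mask]


def baseline_std(E: np.ndarray) -> BaselineStats:
    """Unbiased per-channel std of a spike-free baseline and its channel mean.

    The baseline must have the same duration as the data of interest and at
    least two samples.
    """
    E = np.asarray(E, dtype=float)
    if E.ndim != 2 or E.shape[1] < 2:
        raise ValueError("baseline must be (q, tau) with tau >= 2")
    sigma = E.std(axis=1, ddof=1)
    sigma_bar = float(sigma.mean())
    if sigma_bar == 0:
        raise ValueError("baseline is all-zero: mean std is 0")
    return BaselineStats(sigma=sigma, sigma_bar=sigma_bar,
                         n_channels=E.shape[0])


def snr_transform(M: np.ndarray, G: np.ndarray,
                  stats: BaselineStats) -> tuple[np.ndarray, np.ndarray]:
    """Divide data and lead field by the modality's mean baseline std.

    Applying the same scalar to both sides preserves the forward relation
    M = G J, while rendering the scaled quantities dimensionless.
    """
    if stats.sigma_bar <= 0:
        raise ValueError("mean baseline std must be positive")
    return np.asarray(M, float) / stats.sigma_bar, np.asarray(G, float) / stats.sigma_bar


def estimate_noise_cov(baseline_scaled: np.ndarray) -> np.ndarray:
    """Diagonal noise covariance: per-channel variance of the scaled baseline.

    Returned as the vector of diagonal entries.  A zero-variance channel is an
    error (bad channels should be dropped before fusion).
    """
    E = np.asarray(baseline_scaled, dtype=float)
    if E.shape[1] < 2:
        raise ValueError("need at least two baseline samples")
    var = E.var(axis=1, ddof=1)
    bad = np.flatnonzero(np.ptp(E, axis=1) == 0)  # numerically constant rows
    if bad.size:
        raise ValueError(f"zero-variance baseline channel(s): {bad.tolist()}")
    return var


def drop_bad_channels(M: np.ndarray, G: np.ndarray, E: np.ndarray,
                      labels: list[str] | None = None):
    """Remove channels whose baseline variance is zero, with a logged warning."""
    E = np.asarray(E, float)
    good = np.ptp(E, axis=1) > 0
    if not np.all(good):
        dropped = (np.flatnonzero(~good).tolist() if labels is None
                   else [labels[i] for i in np.flatnonzero(~good)])
        logger.warning("dropping bad channels with zero baseline variance: %s",
                       dropped)
    return M[good], G[good], E[good], good


def concatenate_modalities(
    eeg: tuple[np.ndarray, np.ndarray, np.ndarray] | None,
    meg: tuple[np.ndarray, np.ndarray, np.ndarray] | None,
) -> FusedRecording:
    """Stack scaled (data, gain, baseline) triplets row-wise, EEG block first.

    Either block may be absent (monomodal pipelines degenerate gracefully).
    """
    blocks = []
    for mod, trip in (("EEG", eeg), ("MEG", meg)):
        if trip is None:
            continue
        M, G, E = (np.asarray(a, dtype=float) for a in trip)
        if M.shape[0] != G.shape[0] or M.shape[0] != E.shape[0]:
            raise ValueError(f"{mod}: inconsistent channel counts")
        blocks.append((mod, M, G, E))
    if not blocks:
        raise ValueError("at least one modality is required")
    tau = blocks[0][1].shape[1]
    p = blocks[0][2].shape[1]
    for mod, M, G, E in blocks:
        if M.shape[1] != tau or E.shape[1] != tau:
            raise ValueError(f"{mod}: mismatched number of time samples")
        if G.shape[1] != p:
            raise ValueError(f"{mod}: mismatched number of sources")

    data = np.vstack([b[1] for b in blocks])
    gain = np.vstack([b[2] for b in blocks])
    base = np.vstack([b[3] for b in blocks])
    tags = np.concatenate([np.full(b[1].shape[0], b[0]) for b in blocks])
    return FusedRecording(data=data, gain=gain, baseline=base, modalities=tags,
                          noise_var=estimate_noise_cov(base))


def fuse(
    recordings: dict[str, np.ndarray],
    leadfields: dict[str, LeadField | np.ndarray],
    baselines: dict[str, np.ndarray],
    modalities: tuple[str, ...] = ("EEG", "MEG"),
) -> FusedRecording:
    """Full step-1 pipeline: per-modality SNR transform, then concatenation."""
    triplets: dict[str, tuple] = {}
    for mod in modalities:
        G = leadfields[mod]
        G = G.G if isinstance(G, LeadField) else G
        stats = baseline_std(baselines[mod])
        Ms, Gs = snr_transform(recordings[mod], G, stats)
        Es = baselines[mod] / stats.sigma_bar
        triplets[mod] = (Ms, Gs, Es)
    return concatenate_modalities(triplets.get("EEG"), triplets.get("MEG"))
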
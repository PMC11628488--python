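"""Ocular artifact removal.

The cleaning chain: each run's EEG is high-pass filtered (zero-phase
2nd-order Butterworth, 1 Hz), runs are concatenated in time, PCA reduces the
64 EEG channels to 15 components, FastICA unmixes those, and for each EOG
channel (band-passed 1–10 Hz) the independent component with the highest
absolute Pearson correlation is zeroed before reconstruction.  Fitting and
application are separated so the remover can be estimated on training runs
only and applied to held-out runs.

``EOGRemover`` is a scikit-learn compatible transformer over
(samples x channels) arrays; :func:`fit_eog_remover` / :func:`apply_eog_remover`
wrap it for :class:`ContinuousData`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA, FastICA
from sklearn.exceptions import ConvergenceWarning
from sklearn.utils.validation import check_is_fitted

from .filters import bandpass_filter, highpass_filter
from .synthetic import EOG_CHANNELS, Recording

__all__ = [
    "SchemaError",
    "ConvergenceError",
    "ContinuousData",
    "EOGRemover",
    "highpass_filter",
    "highpass_and_concatenate",
    "fit_eog_remover",
    "apply_eog_remover",
]


class SchemaError(ValueError):
    """Channel sets or sampling rates do not match across inputs."""


class ConvergenceError(RuntimeError):
    """ICA failed to converge within the iteration budget."""

    def __init__(self, message: str, n_iter: int):
        super().__init__(message)
        self.n_iter = n_iter


@dataclass
class ContinuousData:
    """Concatenated continuous multichannel data with run bookkeeping.

    ``run_boundaries`` holds the interior start indices of runs 2..R, so a
    two-run concatenation of lengths (a, b) records ``[a]``.
    """

    data: np.ndarray  # channels x samples
    sampling_rate: float
    channel_names: tuple[str, ...]
    run_boundaries: list[int] = field(default_factory=list)
    events: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        n = self.data.shape[1]
        if any(b <= 0 or b >= n for b in self.run_boundaries):
            raise ValueError("run boundaries must lie strictly inside the data")
        if sorted(self.run_boundaries) != list(self.run_boundaries):
            raise ValueError("run boundaries must be sorted")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def segments(self) -> list[slice]:
        """Per-run sample slices."""
        edges = [0, *self.run_boundaries, self.n_samples]
        return [slice(a, b) for a, b in zip(edges[:-1], edges[1:])]

    def channel_index(self, names: Sequence[str]) -> np.ndarray:
        lut = {ch: i for i, ch in enumerate(self.channel_names)}
        missing = [ch for ch in names if ch not in lut]
        if missing:
            raise SchemaError(f"channels missing: {missing}")
        return np.array([lut[ch] for ch in names])


def highpass_and_concatenate(
    recordings: Sequence[Recording], cutoff: float = 1.0, order: int = 2
) -> ContinuousData:
    """High-pass each run's EEG independently, then concatenate runs in time.

    EOG channels are carried through unfiltered here; the remover band-passes
    them separately when computing IC correlations.
    """
    if not recordings:
        raise ValueError("need at least one recording")
    ref = recordings[0]
    for rec in recordings[1:]:
        if rec.channel_names != ref.channel_names:
            raise SchemaError("recordings have mismatched channel sets")
        if rec.sampling_rate != ref.sampling_rate:
            raise SchemaError("recordings have mismatched sampling rates")
    eog_idx = [i for i, ch in enumerate(ref.channel_names) if ch in EOG_CHANNELS]
    parts, frames, boundaries = [], [], []
    offset = 0
    for rec in recordings:
        filt = highpass_filter(rec.data, rec.sampling_rate, cutoff, order)
        filt[eog_idx] = rec.data[eog_idx]
        parts.append(filt)
        ev = rec.events.copy()
        ev["sample"] += offset
        frames.append(ev)
        offset += rec.data.shape[1]
        boundaries.append(offset)
    return ContinuousData(
        data=np.concatenate(parts, axis=1),
        sampling_rate=ref.sampling_rate,
        channel_names=ref.channel_names,
        run_boundaries=boundaries[:-1],
        events=pd.concat(frames, ignore_index=True),
    )


class EOGRemover(TransformerMixin, BaseEstimator):
    """PCA + FastICA spatial filter zeroing the EOG-correlated components.

    Operates on arrays of shape (n_samples, n_channels) whose columns are the
    64 EEG channels followed by VEOG and HEOG (override with ``eeg_idx`` /
    ``veog_idx`` / ``heog_idx``).  The EEG is reduced to ``n_components``
    principal components, unmixed with FastICA, and for each EOG channel the
    source with the highest |Pearson r| against the 1–10 Hz band-passed EOG
    is marked for removal.  ``transform`` subtracts the marked sources'
    contribution from the EEG columns and is idempotent.

    Parameters
    ----------
    n_components : PCA dimensionality before ICA (15 by default).
    sampling_rate : Hz, used for the EOG 1–10 Hz band-pass.
    eog_band : correlation band-pass for the EOG channels.
    on_nonconvergence : 'warn' keeps the (still usable) decomposition and
        records it; 'raise' raises :class:`ConvergenceError`.
    max_fit_samples : spatial filters are time-invariant, so PCA/ICA (and
        the IC-EOG correlations) are estimated on an evenly strided subset
        of at most this many samples when the input is longer; ``None``
        always uses every sample.
    """

    def __init__(
        self,
        n_components: int = 15,
        sampling_rate: float = 1000.0,
        eog_band: tuple[float, float] = (1.0, 10.0),
        max_iter: int = 1000,
        tol: float = 1e-4,
        random_state: int | None = 0,
        eeg_idx: Sequence[int] | None = None,
        veog_idx: int = -2,
        heog_idx: int = -1,
        on_nonconvergence: str = "warn",
        max_fit_samples: int | None = 200_000,
    ):
        self.n_components = n_components
        self.sampling_rate = sampling_rate
        self.eog_band = eog_band
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state
        self.eeg_idx = eeg_idx
        self.veog_idx = veog_idx
        self.heog_idx = heog_idx
        self.on_nonconvergence = on_nonconvergence
        self.max_fit_samples = max_fit_samples

    def _split(self, X: np.ndarray):
        n_ch = X.shape[1]
        if self.eeg_idx is None:
            eog = {self.veog_idx % n_ch, self.heog_idx % n_ch}
            eeg = np.array([i for i in range(n_ch) if i not in eog])
        else:
            eeg = np.asarray(self.eeg_idx)
        return eeg, self.veog_idx % n_ch, self.heog_idx % n_ch

    def fit(self, X: np.ndarray, y=None) -> "EOGRemover":
        X = np.asarray(X)
        if X.dtype.kind != "f":
            X = X.astype(float)
        eeg_idx, iv, ih = self._split(X)
        if len(eeg_idx) < self.n_components:
            raise SchemaError(
                f"{len(eeg_idx)} EEG channels < {self.n_components} components"
            )
        stride = 1
        if self.max_fit_samples is not None and X.shape[0] > self.max_fit_samples:
            stride = int(np.ceil(X.shape[0] / self.max_fit_samples))
        self.fit_stride_ = stride
        eeg = X[::stride, eeg_idx]
        self.pca_ = PCA(n_components=self.n_components, random_state=self.random_state)
        scores = self.pca_.fit_transform(eeg)
        self.ica_ = FastICA(
            n_components=self.n_components,
            fun="logcosh",
            algorithm="parallel",
            whiten="unit-variance",
            max_iter=self.max_iter,
            tol=self.tol,
            random_state=self.random_state,
        )
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            sources = self.ica_.fit_transform(scores)
        self.converged_ = not any(
            issubclass(w.category, ConvergenceWarning) for w in caught
        )
        self.n_iter_ = int(self.ica_.n_iter_)
        if not self.converged_ and self.on_nonconvergence == "raise":
            raise ConvergenceError(
                f"FastICA did not converge in {self.n_iter_} iterations",
                self.n_iter_,
            )

        eog_filt = bandpass_filter(
            X[:, [iv, ih]].T, self.sampling_rate, self.eog_band
        )[:, ::stride]
        corr = np.empty((2, self.n_components))
        for j in range(2):
            e = eog_filt[j] - eog_filt[j].mean()
            es = np.linalg.norm(e)
            for k in range(self.n_components):
                s = sources[:, k] - sources[:, k].mean()
                denom = es * np.linalg.norm(s)
                corr[j, k] = float(s @ e) / denom if denom > 0 else 0.0
        self.correlations_ = corr
        picks = {
            "VEOG": int(np.argmax(np.abs(corr[0]))),
            "HEOG": int(np.argmax(np.abs(corr[1]))),
        }
        self.ic_for_eog_ = picks
        self.zeroed_ics_ = sorted(set(picks.values()))
        self._eeg_idx_ = eeg_idx
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "zeroed_ics_")
        X = np.asarray(X)
        if X.dtype.kind != "f":
            X = X.astype(float)
        eeg_idx, _, _ = self._split(X)
        if len(eeg_idx) != len(self._eeg_idx_):
            raise SchemaError("channel layout differs from the fitted layout")
        out = X.copy()
        z = list(self.zeroed_ics_)
        if not z:
            return out
        eeg = X[:, eeg_idx]
        scores = self.pca_.transform(eeg)
        centered = scores - self.ica_.mean_
        unmix = self.ica_.components_  # (n_comp, n_feat)
        mixing = self.ica_.mixing_  # (n_feat, n_comp)
        delta_scores = (centered @ unmix[z].T) @ mixing[:, z].T
        out[:, eeg_idx] = eeg - delta_scores @ self.pca_.components_
        return out


def fit_eog_remover(
    cont: ContinuousData, n_components: int = 15, seed: int = 0, **kwargs
) -> EOGRemover:
    """Fit an :class:`EOGRemover` on (already high-passed) continuous data."""
    iv, ih = cont.channel_index(["VEOG", "HEOG"])
    eeg_idx = [
        i for i, ch in enumerate(cont.channel_names) if ch not in EOG_CHANNELS
    ]
    model = EOGRemover(
        n_components=n_components,
        sampling_rate=cont.sampling_rate,
        random_state=seed,
        eeg_idx=eeg_idx,
        veog_idx=int(iv),
        heog_idx=int(ih),
        **kwargs,
    )
    model.fit(cont.data.T)
    model.channel_names_ = cont.channel_names
    return model


def apply_eog_remover(model: EOGRemover, cont: ContinuousData) -> ContinuousData:
    """Project out the fitted EOG components; EOG channels pass unchanged."""
    if getattr(model, "channel_names_", cont.channel_names) != cont.channel_names:
        raise SchemaError("channel set differs from the one the remover was fit on")
    cleaned = model.transform(cont.data.T).T
    return ContinuousData(
        data=cleaned,
        sampling_rate=cont.sampling_rate,
        channel_names=cont.channel_names,
        run_boundaries=list(cont.run_boundaries),
        events=None if cont.events is None else cont.events.copy(),
    )
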
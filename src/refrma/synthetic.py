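"""Synthetic probe-level data with known truth.

The generator emulates the data-generating process assumed by the RMA
convolution model: each probe-set has a latent log2 signal (an
exponentially distributed linear-scale baseline, optionally shifted by a
class effect in informative probe-sets, plus per-sample biological noise);
each probe adds a fixed affinity offset on the log2 scale; each laboratory
adds a per-probe batch shift shared by all of its arrays (multiplicative on
the linear scale); and the observed intensity is the linear-scale signal
plus a normal optical background, truncated positive.  Everything is
deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .probe_io import ChipLayout, ProbeDataError, ProbeMatrix

__all__ = [
    "SimConfig",
    "SimTruth",
    "TwoLabStudy",
    "simulate_probe_data",
    "simulate_two_lab_study",
    "simulate_batch_shift_sweep",
]

_LN2 = float(np.log(2.0))


@dataclass
class SimConfig:
    """Study conditions for the synthetic generator.

    probes_per_set defaults to 11, the typical probe count per probe-set on
    the U133 Plus 2.0 design.  background parameters default to a
    background of N(100, 15) fluorescence units under an exponential signal
    of mean 200, a regime typical of scanned arrays.  batch_shift_sd is the
    SD (log2) of per-probe multiplicative shifts shared within a
    laboratory; 0 means all arrays come from the same lab.
    """

    n_probesets: int = 500
    probes_per_set: int = 11
    n_samples: int = 60
    n_informative: int = 50
    class_effect: float = 1.5
    classes: list[tuple[str, float]] = field(
        default_factory=lambda: [("A", 0.5), ("B", 0.5)])
    background_mu: float = 100.0
    background_sigma: float = 15.0
    signal_mean: float = 200.0
    probe_affinity_sd: float = 1.0
    batch_shift_sd: float = 0.0
    noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_probesets", "probes_per_set", "n_samples"):
            if getattr(self, name) < 1:
                raise ProbeDataError(f"{name} must be >= 1")
        if not 0 <= self.n_informative <= self.n_probesets:
            raise ProbeDataError("n_informative must lie in [0, n_probesets]")
        for name in ("background_sigma", "signal_mean"):
            if getattr(self, name) <= 0:
                raise ProbeDataError(f"{name} must be > 0")
        for name in ("probe_affinity_sd", "batch_shift_sd", "noise_sd", "class_effect"):
            if getattr(self, name) < 0:
                raise ProbeDataError(f"{name} must be >= 0")
        props = np.asarray([p for _, p in self.classes], dtype=float)
        if len(self.classes) < 1 or abs(props.sum() - 1.0) > 1e-9 or np.any(props < 0):
            raise ProbeDataError("class proportions must be nonnegative and sum to 1")


@dataclass
class SimTruth:
    """Ground truth accompanying a simulated probe matrix."""

    labels: list[str]
    signal: pd.DataFrame  # probe-sets x samples, true log2 signal


@dataclass
class TwoLabStudy:
    """A reference cohort plus same-lab and shifted-lab held-out samples."""

    layout: ChipLayout
    reference: ProbeMatrix
    inlab: ProbeMatrix
    exlab: ProbeMatrix
    reference_truth: SimTruth
    inlab_truth: SimTruth
    exlab_truth: SimTruth


def _make_layout(config: SimConfig) -> ChipLayout:
    width = len(str(config.n_probesets))
    probe_ids, mapping = [], {}
    for s in range(config.n_probesets):
        ps = f"ps{s:0{width}d}"
        for p in range(config.probes_per_set):
            pid = f"{ps}_p{p:02d}"
            probe_ids.append(pid)
            mapping[pid] = ps
    return ChipLayout(probe_ids=probe_ids, probe_to_probeset=mapping, chip_id="simchip")


class _ChipStructure:
    """Latent quantities shared by every array of one simulated chip lot:
    probe-set baselines, probe affinities and the class-effect pattern."""

    def __init__(self, config: SimConfig, rng: np.random.Generator):
        self.config = config
        self.layout = _make_layout(config)
        n_ps, ppset = config.n_probesets, config.probes_per_set
        # Exponential(1) linear-scale baselines give the marginal intensity
        # distribution its exponential signal component.
        self.baseline_log2 = np.log2(
            config.signal_mean * np.maximum(rng.exponential(1.0, size=n_ps), 1e-4))
        # Mean-one on the linear scale so the marginal signal mean stays at
        # signal_mean: E[2^N(m, s^2)] = 1 for m = -s^2 ln2 / 2.
        sd = config.probe_affinity_sd
        self.affinity = rng.normal(-sd * sd * _LN2 / 2.0, sd, size=n_ps * ppset)
        # Informative set k boosts class (k mod K) by class_effect.
        n_classes = len(config.classes)
        self.effect = np.zeros((n_ps, n_classes))
        for k in range(config.n_informative):
            self.effect[k, k % n_classes] = config.class_effect

    def batch_shift(self, rng: np.random.Generator, sd: float) -> np.ndarray:
        if sd == 0.0:
            return np.zeros(len(self.layout.probe_ids))
        return rng.normal(-sd * sd * _LN2 / 2.0, sd, size=len(self.layout.probe_ids))

    def sample_arrays_multi_shift(
        self,
        rng: np.random.Generator,
        n: int,
        shift_sds: list[float],
        sample_prefix: str,
    ) -> tuple[dict[float, ProbeMatrix], SimTruth]:
        """One set of arrays rendered under several batch-shift magnitudes.

        Class labels, biological noise, probe signals and optical background
        are drawn once; a single unit shift vector is scaled by each
        requested SD, so the returned matrices form a paired sweep in which
        the batch shift is the only difference between renderings.
        """
        unit = rng.normal(0.0, 1.0, size=len(self.layout.probe_ids))
        draws = self._draw_components(rng, n, sample_prefix)
        out: dict[float, ProbeMatrix] = {}
        for sd in shift_sds:
            shift = sd * unit - sd * sd * _LN2 / 2.0
            out[sd] = self._render(draws, shift)
        return out, draws[-1]

    def sample_arrays(
        self,
        rng: np.random.Generator,
        n: int,
        shift: np.ndarray,
        sample_prefix: str,
    ) -> tuple[ProbeMatrix, SimTruth]:
        draws = self._draw_components(rng, n, sample_prefix)
        return self._render(draws, shift), draws[-1]

    def _draw_components(self, rng: np.random.Generator, n: int, prefix: str):
        cfg = self.config
        labels_pool = [c for c, _ in cfg.classes]
        props = np.asarray([p for _, p in cfg.classes])
        # Deterministic class counts in the stated proportions (largest-
        # remainder rounding), randomly ordered: cohorts in this field are
        # assembled with fixed group sizes, and exact proportions keep the
        # class mix of a reference subset comparable to any other cohort.
        counts = np.floor(props * n).astype(int)
        remainder = props * n - counts
        for k in np.argsort(-remainder)[: n - counts.sum()]:
            counts[k] += 1
        class_idx = rng.permutation(np.repeat(np.arange(len(labels_pool)), counts))
        labels = [labels_pool[i] for i in class_idx]

        noise = rng.normal(0.0, cfg.noise_sd, size=(cfg.n_probesets, n))
        signal_log2 = self.baseline_log2[:, None] + self.effect[:, class_idx] + noise
        background = rng.normal(cfg.background_mu, cfg.background_sigma,
                                size=(len(self.layout.probe_ids), n))
        sample_ids = [f"{prefix}{j:03d}" for j in range(n)]
        signal = pd.DataFrame(signal_log2, index=self.layout.probeset_ids,
                              columns=sample_ids)
        truth = SimTruth(labels=labels, signal=signal)
        return signal_log2, background, sample_ids, truth

    def _render(self, draws, shift: np.ndarray) -> ProbeMatrix:
        signal_log2, background, sample_ids, _ = draws
        probe_log2 = (np.repeat(signal_log2, self.config.probes_per_set, axis=0)
                      + self.affinity[:, None] + shift[:, None])
        observed = np.maximum(np.exp2(probe_log2) + background, 1e-3)
        return ProbeMatrix(list(self.layout.probe_ids), list(sample_ids), observed)


def simulate_probe_data(config: SimConfig) -> tuple[ProbeMatrix, ChipLayout, SimTruth]:
    """Simulate one cohort of probe-level arrays with known truth.

    If ``batch_shift_sd`` > 0 a single per-probe batch shift (shared by all
    arrays, multiplicative on the linear scale) is applied — the cohort then
    represents one laboratory displaced from the chip-lot average.
    """
    rng = np.random.default_rng(config.seed)
    structure = _ChipStructure(config, rng)
    shift = structure.batch_shift(rng, config.batch_shift_sd)
    matrix, truth = structure.sample_arrays(rng, config.n_samples, shift, "s")
    return matrix, structure.layout, truth


def simulate_two_lab_study(config: SimConfig, n_ref: int) -> TwoLabStudy:
    """Simulate a reference cohort plus matched and batch-shifted samples.

    Laboratory A contributes ``n_ref`` reference arrays and
    ``config.n_samples - n_ref`` held-out arrays (the in-lab analog);
    laboratory B contributes the same number of held-out arrays carrying an
    additional per-probe batch shift of SD ``config.batch_shift_sd``
    (the external-lab analog).  All three groups share chip structure
    (baselines, affinities) and the class-effect pattern.
    """
    if n_ref < 2:
        raise ProbeDataError("n_ref must be >= 2")
    if n_ref >= config.n_samples:
        raise ProbeDataError(
            f"n_ref={n_ref} leaves no held-out samples of the configured "
            f"{config.n_samples}"
        )
    rng = np.random.default_rng(config.seed)
    structure = _ChipStructure(config, rng)
    n_held = config.n_samples - n_ref
    no_shift = np.zeros(len(structure.layout.probe_ids))
    reference, ref_truth = structure.sample_arrays(rng, n_ref, no_shift, "ref")
    inlab, in_truth = structure.sample_arrays(rng, n_held, no_shift, "in")
    shift = structure.batch_shift(rng, config.batch_shift_sd)
    exlab, ex_truth = structure.sample_arrays(rng, n_held, shift, "ex")
    return TwoLabStudy(
        layout=structure.layout,
        reference=reference, inlab=inlab, exlab=exlab,
        reference_truth=ref_truth, inlab_truth=in_truth, exlab_truth=ex_truth,
    )


def simulate_batch_shift_sweep(
    config: SimConfig, n_ref: int, shift_sds: list[float]
) -> tuple[ChipLayout, ProbeMatrix, ProbeMatrix, dict[float, ProbeMatrix], SimTruth]:
    """Simulate a reference cohort plus one held-out set rendered under a
    sweep of batch-shift magnitudes.

    Returns (layout, reference, same-lab held-out, {shift_sd: shifted
    held-out}, held-out truth).  The shifted matrices are paired: they share
    every random draw and differ only in the scale applied to one unit
    shift vector, so quality-control metrics can be compared across shift
    magnitudes without simulation noise between levels.
    """
    if n_ref < 2:
        raise ProbeDataError("n_ref must be >= 2")
    if n_ref >= config.n_samples:
        raise ProbeDataError(
            f"n_ref={n_ref} leaves no held-out samples of the configured "
            f"{config.n_samples}"
        )
    rng = np.random.default_rng(config.seed)
    structure = _ChipStructure(config, rng)
    n_held = config.n_samples - n_ref
    no_shift = np.zeros(len(structure.layout.probe_ids))
    reference, _ = structure.sample_arrays(rng, n_ref, no_shift, "ref")
    inlab, _ = structure.sample_arrays(rng, n_held, no_shift, "in")
    swept, truth = structure.sample_arrays_multi_shift(rng, n_held, shift_sds, "sw")
    return structure.layout, reference, inlab, swept, truth
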
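"""Data model and plain-text I/O for probe-level microarray data.

The on-disk formats are deliberately simple: probe intensities are TSV/CSV
tables (probe_id column + one column per sample, linear-scale fluorescence),
the chip layout is a two-column TSV mapping probes to probe-sets, and a
reference archive is a directory of TSV tables plus a JSON manifest with
checksums.  Everything round-trips at full float64 precision (numbers are
written with 17 significant digits).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ProbeMatrix",
    "ChipLayout",
    "ReferenceArchive",
    "ClassifierModel",
    "read_probe_matrix",
    "read_chip_layout",
    "write_chip_layout",
    "save_reference_archive",
    "load_reference_archive",
]

_FLOAT_FMT = "%.17g"


class ProbeDataError(ValueError):
    """Raised when probe-level inputs violate the data contract."""


@dataclass
class ChipLayout:
    """Mapping of probes to probe-sets for one chip design.

    Probe order and probe-set order are the first-appearance order in the
    layout file; this order is canonical everywhere downstream (median-polish
    rows, probe-effect subtraction, quantile vectors).
    """

    probe_ids: list[str]
    probe_to_probeset: dict[str, str]
    chip_id: str = "custom"
    probeset_ids: list[str] = field(default_factory=list)
    _probeset_rows: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self.probe_ids:
            raise ProbeDataError("layout contains no probes")
        if len(set(self.probe_ids)) != len(self.probe_ids):
            raise ProbeDataError("duplicate probe ids in layout")
        if set(self.probe_ids) != set(self.probe_to_probeset):
            raise ProbeDataError("probe id list and probe->probe-set mapping disagree")
        if not self.probeset_ids:
            seen: dict[str, None] = {}
            for p in self.probe_ids:
                seen.setdefault(self.probe_to_probeset[p], None)
            self.probeset_ids = list(seen)
        if not self._probeset_rows:
            idx: dict[str, list[int]] = {ps: [] for ps in self.probeset_ids}
            for i, p in enumerate(self.probe_ids):
                idx[self.probe_to_probeset[p]].append(i)
            self._probeset_rows = {ps: np.asarray(rows, dtype=np.intp) for ps, rows in idx.items()}

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_probesets(self) -> int:
        return len(self.probeset_ids)

    def probe_rows(self, probeset_id: str) -> np.ndarray:
        """Row indices (layout order) of the probes in one probe-set."""
        return self._probeset_rows[probeset_id]


@dataclass
class ProbeMatrix:
    """Raw probe-level intensities: one row per probe, one column per sample.

    Intensities are strictly positive, linear-scale fluorescence values.
    """

    probe_ids: list[str]
    sample_ids: list[str]
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ProbeDataError(
                f"intensity table shape {self.intensities.shape} inconsistent with "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples"
            )
        if len(set(self.probe_ids)) != len(self.probe_ids):
            raise ProbeDataError("duplicate probe ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ProbeDataError("duplicate sample ids")
        if not np.all(np.isfinite(self.intensities)):
            raise ProbeDataError("non-finite intensity values")
        if np.any(self.intensities <= 0):
            i, j = np.argwhere(self.intensities <= 0)[0]
            raise ProbeDataError(
                f"nonpositive intensity at probe {self.probe_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}: {self.intensities[i, j]}"
            )

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.intensities, index=self.probe_ids, columns=self.sample_ids)

    def column(self, sample_id: str) -> np.ndarray:
        return self.intensities[:, self.sample_ids.index(sample_id)]


@dataclass
class ReferenceArchive:
    """Frozen quantities enabling single-sample RMA against a reference cohort.

    quantile_vector : per-rank mean of the sorted, background-corrected
        reference columns (linear scale) — the target distribution for
        quantile mapping of a new array.
    probe_effects : per-probe row effects (log2) from median polish of each
        probe-set block of the quantile-normalized reference.
    probeset_medians / probeset_sds : per-probe-set median and SD (log2) of
        the reference cohort's RMA expression values, used for centering and
        SD rescaling before classification.
    """

    chip_id: str
    n_reference: int
    quantile_vector: np.ndarray
    probe_effects: pd.Series
    probeset_medians: pd.Series
    probeset_sds: pd.Series
    cohort_label: str | None = None

    def __post_init__(self) -> None:
        self.quantile_vector = np.asarray(self.quantile_vector, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.n_reference < 2:
            raise ProbeDataError("reference archive needs >= 2 reference arrays")
        if np.any(np.diff(self.quantile_vector) < 0):
            raise ProbeDataError("quantile vector must be nondecreasing")
        if np.any(self.quantile_vector <= 0):
            raise ProbeDataError("quantile vector entries must be positive")
        if len(self.probe_effects) != len(self.quantile_vector):
            raise ProbeDataError(
                f"probe effects ({len(self.probe_effects)}) and quantile vector "
                f"({len(self.quantile_vector)}) disagree in length"
            )
        if not self.probeset_medians.index.equals(self.probeset_sds.index):
            raise ProbeDataError("probe-set medians and SDs keyed differently")
        if np.any(self.probeset_sds.to_numpy() < 0):
            raise ProbeDataError("probe-set SDs must be nonnegative")

    @property
    def zero_sd_probesets(self) -> list[str]:
        """Probe-sets with zero reference SD (unusable for SD rescaling)."""
        sds = self.probeset_sds
        return list(sds.index[sds.to_numpy() == 0.0])


@dataclass
class ClassifierModel:
    """A trained elastic-net classifier in portable form.

    model_kind is 'dichotomous' (binomial logistic), 'multiclass'
    (multinomial, 0.5 calling threshold) or 'tertile' (binomial resistance
    model called by cohort tertiles).  coefficients maps probeset_id to a
    per-class list of weights (length 1 for dichotomous/tertile models, one
    per class otherwise).  training_sds are the per-probe-set SDs of the
    training cohort, needed for SD rescaling of profiles normalized against a
    different reference.
    """

    model_kind: str
    class_labels: list[str]
    intercepts: np.ndarray
    coefficients: dict[str, np.ndarray]
    training_sds: pd.Series
    alpha: float
    log_lambda: float
    cv_deviance: float
    thresholds: dict[str, float]
    name: str = ""

    def __post_init__(self) -> None:
        self.intercepts = np.atleast_1d(np.asarray(self.intercepts, dtype=float))
        self.coefficients = {k: np.atleast_1d(np.asarray(v, dtype=float)) for k, v in self.coefficients.items()}
        if self.model_kind not in ("dichotomous", "multiclass", "tertile"):
            raise ProbeDataError(f"unknown model kind {self.model_kind!r}")
        if self.model_kind in ("dichotomous", "tertile") and len(self.class_labels) != 2:
            raise ProbeDataError("dichotomous/tertile models need exactly 2 class labels")
        missing = [ps for ps in self.coefficients if ps not in self.training_sds.index]
        if missing:
            raise ProbeDataError(f"coefficients without a training SD: {missing[:5]}")
        if not 0 <= self.alpha <= 1:
            raise ProbeDataError("alpha must lie in [0, 1]")

    @property
    def probeset_ids(self) -> list[str]:
        return list(self.coefficients)

    def save(self, path: str | Path) -> None:
        payload = {
            "model_kind": self.model_kind,
            "class_labels": self.class_labels,
            "intercepts": self.intercepts.tolist(),
            "coefficients": {k: v.tolist() for k, v in self.coefficients.items()},
            "training_sds": {str(k): float(v) for k, v in self.training_sds.items()},
            "alpha": self.alpha,
            "log_lambda": self.log_lambda,
            "cv_deviance": self.cv_deviance,
            "thresholds": self.thresholds,
            "name": self.name,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "ClassifierModel":
        d = json.loads(Path(path).read_text())
        return cls(
            model_kind=d["model_kind"],
            class_labels=d["class_labels"],
            intercepts=np.asarray(d["intercepts"], dtype=float),
            coefficients={k: np.asarray(v, dtype=float) for k, v in d["coefficients"].items()},
            training_sds=pd.Series(d["training_sds"], dtype=float),
            alpha=d["alpha"],
            log_lambda=d["log_lambda"],
            cv_deviance=d["cv_deviance"],
            thresholds=d["thresholds"],
            name=d.get("name", ""),
        )


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep, header=0, dtype={0: str})


def read_chip_layout(path: str | Path, chip_id: str | None = None) -> ChipLayout:
    """Read a two-column probe_id / probeset_id table into a ChipLayout.

    A probe listed twice with the same probe-set is tolerated (collapsed);
    conflicting assignments are an error.
    """
    df = _read_table(path)
    if df.shape[0] == 0:
        raise ProbeDataError(f"layout file {path} is empty")
    if df.shape[1] < 2:
        raise ProbeDataError("layout needs two columns: probe_id, probeset_id")
    probes = df.iloc[:, 0].astype(str).to_numpy()
    sets_ = df.iloc[:, 1].astype(str).to_numpy()
    mapping: dict[str, str] = {}
    order: list[str] = []
    for p, ps in zip(probes, sets_):
        if p in mapping:
            if mapping[p] != ps:
                raise ProbeDataError(
                    f"probe {p!r} assigned to both {mapping[p]!r} and {ps!r}"
                )
            continue
        mapping[p] = ps
        order.append(p)
    return ChipLayout(probe_ids=order, probe_to_probeset=mapping,
                      chip_id=chip_id or Path(path).stem)


def write_chip_layout(layout: ChipLayout, path: str | Path) -> None:
    pd.DataFrame({
        "probe_id": layout.probe_ids,
        "probeset_id": [layout.probe_to_probeset[p] for p in layout.probe_ids],
    }).to_csv(path, sep="\t", index=False)


def read_probe_matrix(path: str | Path, layout: ChipLayout) -> ProbeMatrix:
    """Parse a probe intensity table, restricted and reordered to the layout.

    The first column holds probe ids; the header row holds sample ids; every
    body cell must be a strictly positive number.
    """
    df = _read_table(path)
    if df.shape[1] < 2:
        raise ProbeDataError("intensity table needs a probe_id column plus sample columns")
    probe_col = df.iloc[:, 0].astype(str)
    dupes = probe_col[probe_col.duplicated()].unique()
    if len(dupes):
        raise ProbeDataError(f"duplicate probe ids in {path}: {list(dupes[:5])}")
    df = df.set_index(probe_col.rename("probe_id")).iloc[:, 1:]

    wanted = set(layout.probe_ids)
    orphans = [p for p in df.index if p not in wanted]
    if orphans:
        raise ProbeDataError(
            f"{len(orphans)} probes in {path} absent from layout "
            f"{layout.chip_id!r}: {orphans[:5]}"
        )
    missing = [p for p in layout.probe_ids if p not in df.index]
    if missing:
        raise ProbeDataError(
            f"{len(missing)} layout probes missing from {path}: {missing[:5]}"
        )
    df = df.reindex(layout.probe_ids)

    values = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    bad = np.argwhere(~np.isfinite(values) | (values <= 0))
    if len(bad):
        i, j = bad[0]
        raise ProbeDataError(
            f"invalid intensity at probe {df.index[i]!r}, sample "
            f"{df.columns[j]!r}: {df.iloc[i, j]!r} (must be a positive number)"
        )
    return ProbeMatrix(list(df.index), [str(c) for c in df.columns], values)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def save_reference_archive(archive: ReferenceArchive, dir: str | Path) -> Path:
    """Persist a reference archive as TSV tables + a JSON manifest.

    Returns the manifest path.  Numbers are written with 17 significant
    digits so that save/load round-trips are bit-exact for float64.
    """
    archive.validate()
    out = Path(dir)
    out.mkdir(parents=True, exist_ok=True)

    pd.DataFrame({"quantile": archive.quantile_vector}).to_csv(
        out / "quantiles.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
    archive.probe_effects.rename("probe_effect").rename_axis("probe_id").to_frame().to_csv(
        out / "probe_effects.tsv", sep="\t", float_format=_FLOAT_FMT)
    pd.DataFrame({
        "median": archive.probeset_medians,
        "sd": archive.probeset_sds,
    }).rename_axis("probeset_id").to_csv(
        out / "probeset_stats.tsv", sep="\t", float_format=_FLOAT_FMT)

    files = ["quantiles.tsv", "probe_effects.tsv", "probeset_stats.tsv"]
    manifest = {
        "chip_id": archive.chip_id,
        "n_reference": archive.n_reference,
        "cohort_label": archive.cohort_label,
        "checksums": {f: _sha256(out / f) for f in files},
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return manifest_path


def load_reference_archive(dir: str | Path) -> ReferenceArchive:
    """Load an archive directory written by :func:`save_reference_archive`."""
    root = Path(dir)
    manifest_path = root / "manifest.json"
    if not manifest_path.exists():
        raise ProbeDataError(f"no manifest.json in {root}")
    manifest = json.loads(manifest_path.read_text())
    for fname, expected in manifest["checksums"].items():
        fpath = root / fname
        if not fpath.exists():
            raise ProbeDataError(f"archive file missing: {fname}")
        actual = _sha256(fpath)
        if actual != expected:
            raise ProbeDataError(
                f"checksum mismatch for {fname}: expected {expected[:12]}..., "
                f"got {actual[:12]}... (archive corrupted)"
            )
    quantiles = pd.read_csv(root / "quantiles.tsv", sep="\t",
                            float_precision="round_trip")["quantile"].to_numpy()
    effects = pd.read_csv(root / "probe_effects.tsv", sep="\t", index_col=0,
                          float_precision="round_trip")["probe_effect"]
    effects.index = effects.index.astype(str)
    stats = pd.read_csv(root / "probeset_stats.tsv", sep="\t", index_col=0,
                        float_precision="round_trip")
    stats.index = stats.index.astype(str)
    return ReferenceArchive(
        chip_id=manifest["chip_id"],
        n_reference=manifest["n_reference"],
        quantile_vector=quantiles,
        probe_effects=effects,
        probeset_medians=stats["median"],
        probeset_sds=stats["sd"],
        cohort_label=manifest.get("cohort_label"),
    )
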
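"""Synthetic ECG data generator.

Emulates the clean-beats + clinical-noise protocol: PQRST beats rendered as
sums of Gaussian bumps with per-record morphology jitter, three noise
classes (baseline wander, EMG-like broadband, powerline), amplitude-
controlled linear mixing, and record-disjoint train/val/test splits with
disjoint noise seed streams.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "WaveComponent", "BeatTemplate", "SegmentPair", "Dataset",
    "gen_clean_segments", "render_segment", "gen_noise", "mix",
    "make_dataset", "check_split_hygiene",
    "save_dataset_csv", "load_dataset_csv", "save_dataset_npz", "load_dataset_npz",
]

SEGMENT_LENGTH = 512
FACTOR_RANGE = (0.2, 2.0)
NOISE_KINDS = ("baseline_wander", "emg", "powerline")


@dataclass(frozen=True)
class WaveComponent:
    center: float     # offset from the R peak, seconds
    width: float      # Gaussian std, seconds
    amplitude: float  # mV


@dataclass(frozen=True)
class BeatTemplate:
    sampling_rate: float = 250.0
    heart_rate: float = 60.0
    waves: dict = field(default_factory=lambda: {
        "P": WaveComponent(-0.200, 0.025, 0.15),
        "Q": WaveComponent(-0.032, 0.010, -0.10),
        "R": WaveComponent(0.000, 0.012, 1.00),
        "S": WaveComponent(0.032, 0.010, -0.15),
        "T": WaveComponent(0.240, 0.060, 0.35),
    })
    amp_jitter: float = 0.10     # multiplicative sd on wave amplitudes per record
    width_jitter: float = 0.10   # multiplicative sd on wave widths per record
    timing_jitter: float = 0.01  # sd of per-beat timing offset, seconds
    hr_jitter: float = 0.05      # multiplicative sd on heart rate per record

    def validate(self) -> None:
        r = abs(self.waves["R"].amplitude)
        for name, w in self.waves.items():
            if name != "R" and abs(w.amplitude) >= r:
                raise ValueError(f"R wave must dominate; |{name}| >= |R|")


@dataclass
class SegmentPair:
    clean: np.ndarray
    noisy: np.ndarray
    noise_amplitude_factor: float
    split_tag: str = "train"
    record_id: str = ""
    noise_kind: str = ""
    scaled_noise: np.ndarray | None = None  # the representable difference noisy - clean

    def __post_init__(self):
        if self.clean.shape != self.noisy.shape:
            raise ValueError("clean and noisy segments must have the same length")


def _jittered_template(base: BeatTemplate, rng: np.random.Generator) -> BeatTemplate:
    waves = {}
    for name, w in base.waves.items():
        a = w.amplitude * (1.0 + base.amp_jitter * rng.standard_normal())
        wd = w.width * max(0.2, 1.0 + base.width_jitter * rng.standard_normal())
        waves[name] = WaveComponent(w.center, wd, a)
    hr = base.heart_rate * max(0.5, 1.0 + base.hr_jitter * rng.standard_normal())
    # keep R dominance under jitter
    r = abs(waves["R"].amplitude)
    for name in waves:
        if name != "R" and abs(waves[name].amplitude) >= r:
            w = waves[name]
            waves[name] = WaveComponent(w.center, w.width, 0.5 * r * np.sign(w.amplitude))
    return replace(base, waves=waves, heart_rate=hr)


def render_segment(template: BeatTemplate, phase: float = 0.0,
                   n: int = SEGMENT_LENGTH, beat_jitter: np.random.Generator | None = None
                   ) -> np.ndarray:
    """Render ``n`` samples of repeating PQRST beats; R peaks at
    ``phase + k * RR`` seconds."""
    template.validate()
    fs = template.sampling_rate
    t = np.arange(n) / fs
    rr = 60.0 / template.heart_rate
    dur = n / fs
    k_lo = int(np.floor((-1.0 - phase) / rr))
    k_hi = int(np.ceil((dur + 1.0 - phase) / rr))
    out = np.zeros(n)
    for k in range(k_lo, k_hi + 1):
        center = phase + k * rr
        if beat_jitter is not None and template.timing_jitter > 0:
            center += template.timing_jitter * beat_jitter.standard_normal()
        for w in template.waves.values():
            out += w.amplitude * np.exp(-((t - center - w.center) ** 2) / (2.0 * w.width ** 2))
    return out


def gen_clean_segments(n: int, rng: np.random.Generator,
                       template: BeatTemplate | None = None,
                       n_records: int = 1, record_prefix: str = "rec"):
    """Generate ``n`` clean 512-sample segments assigned round-robin to
    ``n_records`` records, each with its own jittered morphology.

    Returns ``(segments, record_ids)`` with segments of shape (n, 512).
    """
    if n < 1:
        raise ValueError("need n >= 1")
    base = template if template is not None else BeatTemplate()
    base.validate()
    templates = [_jittered_template(base, rng) for _ in range(n_records)]
    segments = np.empty((n, SEGMENT_LENGTH))
    record_ids = []
    for i in range(n):
        r = i % n_records
        tpl = templates[r]
        rr = 60.0 / tpl.heart_rate
        phase = rng.uniform(0.0, rr)
        segments[i] = render_segment(tpl, phase, beat_jitter=rng)
        record_ids.append(f"{record_prefix}{r:03d}")
    return segments, record_ids


# ----------------------------------------------------------------------
def gen_noise(kind: str, length: int, rng: np.random.Generator,
              params: dict | None = None) -> np.ndarray:
    """Zero-mean noise of one clinical class.

    baseline_wander: low-pass filtered Gaussian noise (< ~0.35 Hz);
    emg: band-pass filtered Gaussian noise (25-100 Hz);
    powerline: pure sinusoid at the line frequency with random phase.
    """
    p = {"fs": 250.0, "line_freq": 50.0, "bw_cutoff": 0.35, "emg_band": (25.0, 100.0)}
    if params:
        p.update(params)
    fs = p["fs"]
    if kind == "baseline_wander":
        white = rng.standard_normal(length + 2048)
        sos = sps.butter(4, p["bw_cutoff"], btype="low", fs=fs, output="sos")
        x = sps.sosfiltfilt(sos, white)[1024:1024 + length]
    elif kind == "emg":
        white = rng.standard_normal(length + 512)
        sos = sps.butter(4, p["emg_band"], btype="band", fs=fs, output="sos")
        x = sps.sosfiltfilt(sos, white)[256:256 + length]
    elif kind == "powerline":
        t = np.arange(length) / fs
        x = np.sin(2.0 * np.pi * p["line_freq"] * t + rng.uniform(0.0, 2.0 * np.pi))
    else:
        raise ValueError(f"unknown noise kind {kind!r}")
    return x - x.mean()


def mix(clean: np.ndarray, noise: np.ndarray, amplitude_factor: float,
        split_tag: str = "train", record_id: str = "", noise_kind: str = "") -> SegmentPair:
    """Linearly superimpose peak-normalised noise onto a clean segment.

    ``noisy = clean + factor * (noise / peak|noise|) * peak|clean|`` — the
    factor is the ratio of scaled-noise peak to clean-signal peak.
    """
    clean = np.asarray(clean, dtype=np.float64)
    noise = np.asarray(noise, dtype=np.float64)
    if clean.shape != noise.shape:
        raise ValueError(f"length mismatch: {clean.shape} vs {noise.shape}")
    if not (FACTOR_RANGE[0] <= amplitude_factor <= FACTOR_RANGE[1]):
        raise ValueError(f"amplitude factor {amplitude_factor} outside {FACTOR_RANGE}")
    peak_c = np.max(np.abs(clean))
    peak_n = np.max(np.abs(noise))
    if peak_c == 0.0 or peak_n == 0.0:
        raise ValueError("degenerate input: zero-peak clean or noise segment")
    scaled = (amplitude_factor * (noise / peak_n)) * peak_c
    noisy = clean + scaled
    # store the representable difference so additivity is assertable bit-exactly
    return SegmentPair(clean, noisy, float(amplitude_factor), split_tag, record_id,
                       noise_kind, scaled_noise=noisy - clean)


# ----------------------------------------------------------------------
@dataclass
class Dataset:
    splits: dict                      # split name -> list[SegmentPair]
    noise_seeds: dict                 # split name -> seed entropy tuple
    seed: int

    def __getitem__(self, split: str):
        return self.splits[split]


def make_dataset(n_records_train: int, n_records_test: int, segments_per_record: int,
                 seed: int, template: BeatTemplate | None = None,
                 noise_kinds: tuple = NOISE_KINDS) -> Dataset:
    """Record- and noise-disjoint train/val/test segment collections.

    The train record pool is split 70/30 by record into train/val; test
    records and test noise streams are generated from separate seed
    branches, so no record morphology or noise realisation is shared
    across splits.  Amplitude factors are uniform on [0.2, 2.0].
    """
    if n_records_train < 2 or n_records_test < 1 or segments_per_record < 1:
        raise ValueError("need >= 2 train records, >= 1 test record, >= 1 segment per record")
    root = np.random.SeedSequence(seed)
    ss_trainval_rec, ss_test_rec, ss_train_noise, ss_val_noise, ss_test_noise, ss_misc = \
        root.spawn(6)
    rng_trainval = np.random.default_rng(ss_trainval_rec)
    rng_test = np.random.default_rng(ss_test_rec)
    noise_rngs = {
        "train": np.random.default_rng(ss_train_noise),
        "val": np.random.default_rng(ss_val_noise),
        "test": np.random.default_rng(ss_test_noise),
    }
    misc = np.random.default_rng(ss_misc)

    n_val = int(round(0.3 * n_records_train))
    n_val = min(max(n_val, 1), n_records_train - 1)

    segs_tv, rec_tv = gen_clean_segments(
        n_records_train * segments_per_record, rng_trainval, template,
        n_records=n_records_train, record_prefix="tr")
    segs_te, rec_te = gen_clean_segments(
        n_records_test * segments_per_record, rng_test, template,
        n_records=n_records_test, record_prefix="te")

    val_records = {f"tr{r:03d}" for r in
                   misc.choice(n_records_train, size=n_val, replace=False)}
    splits: dict[str, list[SegmentPair]] = {"train": [], "val": [], "test": []}
    for segments, records, base_split in ((segs_tv, rec_tv, "trainval"),
                                          (segs_te, rec_te, "test")):
        for seg, rec in zip(segments, records):
            if base_split == "test":
                split = "test"
            else:
                split = "val" if rec in val_records else "train"
            kind = noise_kinds[misc.integers(len(noise_kinds))]
            noise = gen_noise(kind, seg.size, noise_rngs[split])
            factor = misc.uniform(*FACTOR_RANGE)
            splits[split].append(mix(seg, noise, factor, split, rec, kind))
    noise_seeds = {k: tuple(ss.entropy if isinstance(ss.entropy, tuple) else (ss.entropy,))
                   + tuple(ss.spawn_key)
                   for k, ss in (("train", ss_train_noise), ("val", ss_val_noise),
                                 ("test", ss_test_noise))}
    return Dataset(splits, noise_seeds, seed)


def check_split_hygiene(dataset: Dataset) -> dict:
    """Machine check of record- and noise-seed disjointness across splits."""
    names = list(dataset.splits)
    record_sets = {k: {p.record_id for p in v} for k, v in dataset.splits.items()}
    record_overlaps = {}
    seed_overlaps = {}
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            record_overlaps[(a, b)] = sorted(record_sets[a] & record_sets[b])
            same_seed = dataset.noise_seeds.get(a) == dataset.noise_seeds.get(b)
            seed_overlaps[(a, b)] = [dataset.noise_seeds[a]] if same_seed else []
    clean = (not any(record_overlaps.values())) and (not any(seed_overlaps.values()))
    return {"ok": clean, "record_overlaps": record_overlaps, "noise_seed_overlaps": seed_overlaps}


# ----------------------------------------------------------------------
def _meta_frame(pairs) -> pd.DataFrame:
    return pd.DataFrame({
        "record_id": [p.record_id for p in pairs],
        "split": [p.split_tag for p in pairs],
        "factor": [p.noise_amplitude_factor for p in pairs],
        "kind": [p.noise_kind for p in pairs],
    })


def _all_pairs(dataset: Dataset):
    return [p for split in ("train", "val", "test") for p in dataset.splits.get(split, [])]


def save_dataset_csv(dataset: Dataset, directory, prefix: str = "segments") -> dict:
    """One row per segment, columns = samples; metadata in a sidecar CSV."""
    import pathlib
    directory = pathlib.Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pairs = _all_pairs(dataset)
    paths = {
        "clean": directory / f"{prefix}_clean.csv",
        "noisy": directory / f"{prefix}_noisy.csv",
        "meta": directory / f"{prefix}_meta.csv",
    }
    pd.DataFrame(np.stack([p.clean for p in pairs])).to_csv(paths["clean"], index=False, header=False)
    pd.DataFrame(np.stack([p.noisy for p in pairs])).to_csv(paths["noisy"], index=False, header=False)
    _meta_frame(pairs).to_csv(paths["meta"], index=False)
    return paths


def _rebuild(clean, noisy, meta, seed=0) -> Dataset:
    splits: dict[str, list[SegmentPair]] = {"train": [], "val": [], "test": []}
    for i, row in meta.iterrows():
        pair = SegmentPair(clean[i], noisy[i], float(row["factor"]), str(row["split"]),
                           str(row["record_id"]), str(row["kind"]),
                           scaled_noise=noisy[i] - clean[i])
        splits.setdefault(pair.split_tag, []).append(pair)
    return Dataset(splits, {}, seed)


def load_dataset_csv(directory, prefix: str = "segments") -> Dataset:
    import pathlib
    directory = pathlib.Path(directory)
    clean = pd.read_csv(directory / f"{prefix}_clean.csv", header=None).to_numpy(dtype=np.float64)
    noisy = pd.read_csv(directory / f"{prefix}_noisy.csv", header=None).to_numpy(dtype=np.float64)
    meta = pd.read_csv(directory / f"{prefix}_meta.csv")
    return _rebuild(clean, noisy, meta)


def save_dataset_npz(dataset: Dataset, path, meta_path) -> None:
    """Binary array file plus the same metadata sidecar CSV."""
    pairs = _all_pairs(dataset)
    np.savez(path, clean=np.stack([p.clean for p in pairs]),
             noisy=np.stack([p.noisy for p in pairs]))
    _meta_frame(pairs).to_csv(meta_path, index=False)


def load_dataset_npz(path, meta_path) -> Dataset:
    with np.load(path) as data:
        clean, noisy = data["clean"], data["noisy"]
    meta = pd.read_csv(meta_path)
    return _rebuild(clean, noisy, meta)


def load_wfdb_record(record_name, directory):  # pragma: no cover - optional path
    """Optional ingestion of a PhysioNet WFDB record (requires ``wfdb``)."""
    try:
        import wfdb
    except ImportError as exc:
        raise ImportError("real-data ingestion requires the optional 'wfdb' package") from exc
    rec = wfdb.rdrecord(str(record_name), pn_dir=None if directory is None else str(directory))
    return np.asarray(rec.p_signal[:, 0], dtype=np.float64), float(rec.fs)
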
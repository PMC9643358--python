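"""Synthetic scalp-EEG-like recordings with known time-varying coupling graphs.

Emulates the statistical structure of clinical seizure sessions at desk scale:
20 channels grouped into four lobes (frontal, temporal, occipital, parietal),
250 Hz sampling, an annotated onset interval, and seven seizure-type labels
(FN, GN, SP, CP, AB, TN, TC) realized as distinct planted coupling-graph
templates. The generative model is a piecewise-stationary first-order vector
autoregression x_t = A_state x_{t-1} + eta_t: its state coupling matrix is
exactly the ground-truth connectivity a graph generator should recover.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "LOBES", "CLASS_LABELS", "TABLE1_CASES",
    "Recording", "GroundTruthConnectivity",
    "UnknownTemplateError", "ParseError",
    "default_channel_names", "lobe_map", "default_electrode_coords",
    "template_coupling", "template_mask",
    "generate_recording", "class_balance_plan",
    "write_recording", "read_recording",
    "write_truth", "read_truth",
]

LOBES = ("frontal", "temporal", "occipital", "parietal")
_LOBE_PREFIX = {"frontal": "F", "temporal": "T", "occipital": "O", "parietal": "P"}

CLASS_LABELS = ("FN", "GN", "SP", "CP", "AB", "TN", "TC")

#: Per-type case counts of the clinical corpus (MY excluded for scarcity).
TABLE1_CASES = {"FN": 1836, "GN": 583, "SP": 52, "CP": 367,
                "AB": 99, "TN": 62, "TC": 48}

#: Diagonal AR coefficient of the resting state and target spectral radius
#: of onset coupling matrices (< 1 keeps every state stationary).
_RESTING_AR = 0.5
_ONSET_RADIUS = 0.9
_ONSET_DIAG = 0.4
#: Template coupling magnitudes are drawn once from this fixed seed so the
#: seven class templates are stable across runs and processes.
_TEMPLATE_SEED = 20221108

#: Onset interval as a fraction of the recording, matching the worked example
#: in which a 150-s session has its onset annotated at [31 s, 128 s).
_ONSET_FRAC = (31.0 / 150.0, 128.0 / 150.0)


class UnknownTemplateError(ValueError):
    """Raised for a template id outside the seven classes plus 'resting'."""


class ParseError(ValueError):
    """Raised when a recording file header cannot be interpreted."""


@dataclass
class Recording:
    """A multichannel recording plus its annotation.

    signal is [n_channels x n_samples] in microvolt-scale arbitrary units.
    onset is a half-open interval [start_s, end_s) in seconds or None.
    """

    signal: np.ndarray
    fs: float
    channel_names: list[str]
    lobe_of: dict[str, str]
    onset: tuple[float, float] | None = None
    label: str = "resting"

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if self.signal.ndim != 2:
            raise ValueError("signal must be a 2-D [channels x samples] array")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.channel_names) != self.signal.shape[0]:
            raise ValueError("channel_names length must match signal rows")
        for name in self.channel_names:
            if name not in self.lobe_of:
                raise ValueError(f"channel {name!r} has no lobe assignment")
        if self.onset is not None:
            start, end = self.onset
            if not (0 <= start < end <= self.n_samples / self.fs):
                raise ValueError("onset interval must satisfy 0 <= start < end <= duration")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class GroundTruthConnectivity:
    """Piecewise-constant true coupling: (interval, matrix) states."""

    states: list[tuple[tuple[float, float], np.ndarray]]
    class_template_id: str = "resting"

    def onset_coupling(self) -> np.ndarray:
        """The coupling matrix of the widest non-resting state (or the only state)."""
        best = max(self.states, key=lambda s: np.abs(s[1] - np.diag(np.diag(s[1]))).sum())
        return best[1]


# ---------------------------------------------------------------------------
# channel layout

def default_channel_names(n_channels: int = 20) -> list[str]:
    """Channel names F1..,T1..,O1..,P1.. split as evenly as possible over lobes."""
    if n_channels < 4:
        raise ValueError("need at least one channel per lobe")
    per = [n_channels // 4 + (1 if i < n_channels % 4 else 0) for i in range(4)]
    names = []
    for lobe, k in zip(LOBES, per):
        names += [f"{_LOBE_PREFIX[lobe]}{i + 1}" for i in range(k)]
    return names


def lobe_map(channel_names: list[str]) -> dict[str, str]:
    prefix_to_lobe = {v: k for k, v in _LOBE_PREFIX.items()}
    out = {}
    for name in channel_names:
        lobe = prefix_to_lobe.get(name[0].upper())
        if lobe is None:
            raise ValueError(f"cannot infer lobe from channel name {name!r}")
        out[name] = lobe
    return out


def default_electrode_coords(n_channels: int = 20) -> np.ndarray:
    """Deterministic 3-D positions: four lobe clusters on a unit hemisphere."""
    names = default_channel_names(n_channels)
    centers = {
        "frontal": np.array([0.0, 0.8, 0.6]),
        "temporal": np.array([0.9, 0.0, 0.4]),
        "occipital": np.array([0.0, -0.8, 0.6]),
        "parietal": np.array([-0.6, 0.0, 0.8]),
    }
    lobes = lobe_map(names)
    rng = np.random.default_rng(7)
    coords = np.empty((n_channels, 3))
    for i, name in enumerate(names):
        jitter = rng.normal(scale=0.12, size=3)
        coords[i] = centers[lobes[name]] + jitter
    return coords


# ---------------------------------------------------------------------------
# class templates

def _index_groups(names: list[str]) -> dict[str, list[int]]:
    groups: dict[str, list[int]] = {lobe: [] for lobe in LOBES}
    lm = lobe_map(names)
    for i, n in enumerate(names):
        groups[lm[n]].append(i)
    return groups


def template_mask(template_id: str, n_channels: int = 20) -> np.ndarray:
    """Binary symmetric mask of which channel pairs a template couples.

    FN: within-frontal block. GN: index-matched cliques spanning all four
    lobes (a sparse global web). SP: within-temporal. CP: within-temporal
    plus index-matched temporal-frontal pairs. AB: bilateral index-matched
    frontal-parietal pairs. TN: within-parietal. TC: the GN web plus the
    within-frontal block. 'resting' couples nothing.
    """
    names = default_channel_names(n_channels)
    groups = _index_groups(names)
    M = np.zeros((n_channels, n_channels))

    def block(idx):
        for a in idx:
            for b in idx:
                if a != b:
                    M[a, b] = 1.0

    def matched(l1, l2):
        for a, b in zip(groups[l1], groups[l2]):
            M[a, b] = M[b, a] = 1.0

    def web():
        depth = min(len(groups[l]) for l in LOBES)
        for k in range(depth):
            idx = [groups[l][k] for l in LOBES]
            block(idx)

    if template_id == "resting":
        pass
    elif template_id == "FN":
        block(groups["frontal"])
    elif template_id == "GN":
        web()
    elif template_id == "SP":
        block(groups["temporal"])
    elif template_id == "CP":
        block(groups["temporal"])
        matched("temporal", "frontal")
    elif template_id == "AB":
        matched("frontal", "parietal")
    elif template_id == "TN":
        block(groups["parietal"])
    elif template_id == "TC":
        web()
        block(groups["frontal"])
    else:
        raise UnknownTemplateError(f"unknown template id {template_id!r}")
    return M


def template_coupling(template_id: str, n_channels: int = 20) -> np.ndarray:
    """The onset-state VAR coupling matrix of one template.

    Off-diagonal magnitudes are drawn once per template from a fixed seed,
    symmetrized, and scaled so the full matrix (with diagonal AR term) has
    spectral radius _ONSET_RADIUS < 1.
    """
    if template_id == "resting":
        return np.eye(n_channels) * _RESTING_AR
    mask = template_mask(template_id, n_channels)
    seed = _TEMPLATE_SEED + CLASS_LABELS.index(template_id)
    rng = np.random.default_rng(seed)
    W = rng.uniform(0.5, 1.0, size=mask.shape)
    W = np.triu(W, 1)
    W = (W + W.T) * mask
    A = np.eye(n_channels) * _ONSET_DIAG + W
    radius = np.max(np.abs(np.linalg.eigvals(A)))
    # shrink only the off-diagonal part onto the target radius
    lo, hi = 0.0, 1.0
    for _ in range(60):
        c = 0.5 * (lo + hi)
        r = np.max(np.abs(np.linalg.eigvals(np.eye(n_channels) * _ONSET_DIAG + c * W)))
        if r > _ONSET_RADIUS:
            hi = c
        else:
            lo = c
    A = np.eye(n_channels) * _ONSET_DIAG + lo * W
    assert np.max(np.abs(np.linalg.eigvals(A))) < 1.0, radius
    return A


# ---------------------------------------------------------------------------
# generation

def default_onset(duration_s: float) -> tuple[float, float]:
    """Default annotated onset: the worked-example fractions of the duration."""
    start = round(duration_s * _ONSET_FRAC[0])
    end = round(duration_s * _ONSET_FRAC[1])
    return float(start), float(end)


def generate_recording(template_id: str, duration_s: float = 150.0,
                       fs: float = 250.0, noise_sd: float = 1.0,
                       seed: int = 0, n_channels: int = 20,
                       onset: tuple[float, float] | None = None,
                       ) -> tuple[Recording, GroundTruthConnectivity]:
    """Simulate one recording under a piecewise VAR(1) with planted coupling.

    Resting recordings use near-diagonal (here: exactly diagonal) coupling
    throughout. Seizure-class recordings switch to the template coupling on
    the onset interval and back to resting coupling outside it. Identical
    seeds give bit-identical output.
    """
    if duration_s <= 0 or fs <= 0:
        raise ValueError("duration and sampling rate must be positive")
    if duration_s < 20:
        raise ValueError("duration must be at least 20 s")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    if template_id != "resting" and template_id not in CLASS_LABELS:
        raise UnknownTemplateError(f"unknown template id {template_id!r}")

    names = default_channel_names(n_channels)
    n_samples = int(round(duration_s * fs))
    a_rest = template_coupling("resting", n_channels)

    if template_id == "resting":
        states = [((0.0, duration_s), a_rest)]
        rec_onset = None
    else:
        if onset is None:
            onset = default_onset(duration_s)
        start, end = onset
        a_on = template_coupling(template_id, n_channels)
        states = []
        if start > 0:
            states.append(((0.0, start), a_rest))
        states.append(((start, end), a_on))
        if end < duration_s:
            states.append(((end, duration_s), a_rest))
        rec_onset = (float(start), float(end))

    rng = np.random.default_rng(seed)
    x = np.zeros(n_channels)
    for _ in range(250):  # burn-in in the first state
        x = states[0][1] @ x + rng.normal(scale=noise_sd, size=n_channels)
    signal = np.empty((n_channels, n_samples))
    for (t0, t1), A in states:
        i0, i1 = int(round(t0 * fs)), int(round(t1 * fs))
        eta = rng.normal(scale=noise_sd, size=(i1 - i0, n_channels))
        for t in range(i0, i1):
            x = A @ x + eta[t - i0]
            signal[:, t] = x

    rec = Recording(signal=signal, fs=fs, channel_names=names,
                    lobe_of=lobe_map(names), onset=rec_onset, label=template_id)
    truth = GroundTruthConnectivity(states=states, class_template_id=template_id)
    return rec, truth


def class_balance_plan(total_cases: int) -> dict[str, int]:
    """Apportion cases over the seven classes proportionally to the corpus.

    Largest-remainder apportionment against the clinical per-type counts,
    with a minimum of one case per class (rebalanced from the largest
    classes), so every class is represented whenever total_cases >= 7.
    """
    if total_cases < 7:
        raise ValueError("total_cases must be at least 7 (one per class)")
    total_ref = sum(TABLE1_CASES.values())
    quotas = {k: total_cases * v / total_ref for k, v in TABLE1_CASES.items()}
    plan = {k: int(np.floor(q)) for k, q in quotas.items()}
    remainder = total_cases - sum(plan.values())
    order = sorted(CLASS_LABELS, key=lambda k: (-(quotas[k] - plan[k]), CLASS_LABELS.index(k)))
    for k in order[:remainder]:
        plan[k] += 1
    # enforce at least one case per class
    while min(plan.values()) == 0:
        zero = next(k for k in CLASS_LABELS if plan[k] == 0)
        donor = max(CLASS_LABELS, key=lambda k: (plan[k], -CLASS_LABELS.index(k)))
        plan[donor] -= 1
        plan[zero] += 1
    assert sum(plan.values()) == total_cases
    return plan


# ---------------------------------------------------------------------------
# recording I/O: columnar text dialect and minimal EDF

def write_recording(rec: Recording, path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".edf":
        _write_edf(rec, path)
    else:
        _write_text(rec, path)


def read_recording(path) -> Recording:
    path = Path(path)
    if path.suffix.lower() == ".edf":
        return _read_edf(path)
    return _read_text(path)


def _write_text(rec: Recording, path: Path) -> None:
    """Columnar text dialect: '#' header lines, then one sample per row."""
    with open(path, "w") as f:
        f.write("# channels: " + ",".join(rec.channel_names) + "\n")
        f.write(f"# fs: {rec.fs!r}\n")
        f.write("# lobes: " + ",".join(f"{c}={rec.lobe_of[c]}"
                                       for c in rec.channel_names) + "\n")
        if rec.onset is None:
            f.write("# onset: none\n")
        else:
            f.write(f"# onset: {rec.onset[0]!r} {rec.onset[1]!r}\n")
        f.write(f"# label: {rec.label}\n")
        np.savetxt(f, rec.signal.T, fmt="%.8e", delimiter="\t")


def _read_text(path: Path) -> Recording:
    header: dict[str, str] = {}
    body_start = 0
    with open(path) as f:
        lines = f.readlines()
    for i, line in enumerate(lines):
        if not line.startswith("#"):
            body_start = i
            break
        stripped = line[1:].strip()
        if ":" not in stripped:
            raise ParseError(f"malformed header line {i + 1}: {line.rstrip()!r}")
        key, _, value = stripped.partition(":")
        header[key.strip()] = value.strip()
    else:
        body_start = len(lines)
    for required in ("channels", "fs"):
        if required not in header:
            raise ParseError(f"missing required header field {required!r}")
    names = header["channels"].split(",")
    try:
        fs = float(header["fs"])
    except ValueError as exc:
        raise ParseError(f"unreadable fs value {header['fs']!r}") from exc
    if "lobes" in header:
        lobes = dict(item.split("=") for item in header["lobes"].split(","))
    else:
        lobes = lobe_map(names)
    onset_field = header.get("onset", "none")
    onset = None
    if onset_field != "none":
        parts = onset_field.split()
        if len(parts) != 2:
            raise ParseError(f"malformed onset field {onset_field!r}")
        onset = (float(parts[0]), float(parts[1]))
    signal = np.loadtxt(lines[body_start:], delimiter="\t", ndmin=2).T
    return Recording(signal=signal, fs=fs, channel_names=names, lobe_of=lobes,
                     onset=onset, label=header.get("label", "resting"))


# EDF: 256-byte main header + 256 bytes per signal, then 16-bit LE samples
# in 1-second data records. Annotation metadata rides in the 80-character
# 'recording id' header field.

def _edf_str(value: str, width: int) -> bytes:
    s = value[:width].ljust(width)
    return s.encode("ascii")


def _write_edf(rec: Recording, path: Path) -> None:
    fs_int = int(round(rec.fs))
    if abs(fs_int - rec.fs) > 1e-9:
        raise ValueError("EDF export requires an integer sampling rate")
    spr = fs_int  # samples per 1-s record
    n_records = int(np.ceil(rec.n_samples / spr))
    padded = np.zeros((rec.n_channels, n_records * spr))
    padded[:, :rec.n_samples] = rec.signal

    def _fit8(v: float) -> float:
        # the header stores 8 ASCII chars; scale with exactly what is stored
        for prec in range(6, 0, -1):
            s = f"{v:.{prec}g}"
            if len(s) <= 8:
                return float(s)
        return float(f"{v:.0e}")

    phys_min = np.array([_fit8(v) for v in padded.min(axis=1)])
    phys_max = np.array([_fit8(v) for v in padded.max(axis=1)])
    phys_min = np.minimum(phys_min, padded.min(axis=1))
    phys_max = np.maximum(phys_max, padded.max(axis=1))
    phys_min = np.array([_fit8(v - abs(v) * 1e-5 - 1e-12) for v in phys_min])
    phys_max = np.array([_fit8(v + abs(v) * 1e-5 + 1e-12) for v in phys_max])
    flat = phys_max - phys_min < 1e-12
    phys_max[flat] = phys_min[flat] + 1.0
    dig_min, dig_max = -32768, 32767

    if rec.onset is None:
        meta = f"label={rec.label};onset=none;n={rec.n_samples}"
    else:
        meta = f"label={rec.label};onset={rec.onset[0]}-{rec.onset[1]};n={rec.n_samples}"

    ns = rec.n_channels
    with open(path, "wb") as f:
        f.write(_edf_str("0", 8))
        f.write(_edf_str("X X X X", 80))                      # patient id
        f.write(_edf_str(meta, 80))                           # recording id
        f.write(_edf_str("01.01.20", 8))
        f.write(_edf_str("00.00.00", 8))
        f.write(_edf_str(str(256 * (1 + ns)), 8))
        f.write(_edf_str("", 44))
        f.write(_edf_str(str(n_records), 8))
        f.write(_edf_str("1", 8))                             # record duration s
        f.write(_edf_str(str(ns), 4))
        for name in rec.channel_names:
            f.write(_edf_str(name, 16))
        for name in rec.channel_names:
            f.write(_edf_str(rec.lobe_of[name], 80))          # transducer field
        for _ in range(ns):
            f.write(_edf_str("uV", 8))
        for v in phys_min:
            f.write(_edf_str(f"{v:.8g}"[:8], 8))
        for v in phys_max:
            f.write(_edf_str(f"{v:.8g}"[:8], 8))
        for _ in range(ns):
            f.write(_edf_str(str(dig_min), 8))
        for _ in range(ns):
            f.write(_edf_str(str(dig_max), 8))
        for _ in range(ns):
            f.write(_edf_str("", 80))                         # prefiltering
        for _ in range(ns):
            f.write(_edf_str(str(spr), 8))
        for _ in range(ns):
            f.write(_edf_str("", 32))

        scale = (phys_max - phys_min) / (dig_max - dig_min)
        for r in range(n_records):
            chunk = padded[:, r * spr:(r + 1) * spr]
            dig = np.round((chunk - phys_min[:, None]) / scale[:, None] + dig_min)
            dig = np.clip(dig, dig_min, dig_max).astype("<i2")
            f.write(dig.tobytes())


def _read_edf(path: Path) -> Recording:
    with open(path, "rb") as f:
        head = f.read(256)
        if len(head) < 256:
            raise ParseError("truncated EDF header")
        meta = head[88:168].decode("ascii").strip()
        try:
            n_records = int(head[236:244].decode().strip())
            ns = int(head[252:256].decode().strip())
        except ValueError as exc:
            raise ParseError("unreadable EDF record counts") from exc
        sig = f.read(256 * ns)

        def field(offset, width, count=ns):
            out = []
            for i in range(count):
                start = offset + i * width
                out.append(sig[start:start + width].decode("ascii").strip())
            return out

        names = field(0, 16)
        transducers = field(16 * ns, 80)
        phys_min = np.array([float(v) for v in field(16 * ns + 80 * ns + 8 * ns, 8)])
        phys_max = np.array([float(v) for v in field(16 * ns + 80 * ns + 16 * ns, 8)])
        dig_min = np.array([float(v) for v in field(16 * ns + 80 * ns + 24 * ns, 8)])
        dig_max = np.array([float(v) for v in field(16 * ns + 80 * ns + 32 * ns, 8)])
        spr = [int(v) for v in field(16 * ns + 80 * ns + 40 * ns + 80 * ns, 8)]
        raw = f.read()

    fs = float(spr[0])
    per_record = sum(spr)
    data = np.frombuffer(raw, dtype="<i2").reshape(n_records, per_record)
    signal = np.empty((ns, n_records * spr[0]))
    offs = np.cumsum([0] + spr)
    scale = (phys_max - phys_min) / (dig_max - dig_min)
    for c in range(ns):
        dig = data[:, offs[c]:offs[c + 1]].reshape(-1).astype(float)
        signal[c] = (dig - dig_min[c]) * scale[c] + phys_min[c]

    fields = dict(item.split("=", 1) for item in meta.split(";") if "=" in item)
    label = fields.get("label", "resting")
    onset = None
    if fields.get("onset", "none") != "none":
        a, _, b = fields["onset"].partition("-")
        onset = (float(a), float(b))
    n_samples = int(fields.get("n", signal.shape[1]))
    signal = signal[:, :n_samples]

    lobes = {}
    for name, t in zip(names, transducers):
        lobes[name] = t if t in LOBES else lobe_map([name])[name]
    return Recording(signal=signal, fs=fs, channel_names=names, lobe_of=lobes,
                     onset=onset, label=label)


# ---------------------------------------------------------------------------
# ground-truth JSON

def write_truth(truth: GroundTruthConnectivity, path) -> None:
    doc = {
        "class_template_id": truth.class_template_id,
        "states": [
            {"start_s": t0, "end_s": t1, "matrix": A.tolist()}
            for (t0, t1), A in truth.states
        ],
    }
    Path(path).write_text(json.dumps(doc))


def read_truth(path) -> GroundTruthConnectivity:
    doc = json.loads(Path(path).read_text())
    states = [((s["start_s"], s["end_s"]), np.asarray(s["matrix"], float))
              for s in doc["states"]]
    return GroundTruthConnectivity(states=states,
                                   class_template_id=doc["class_template_id"])
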
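"""Synthetic dioecious genomes, pooled reads, and validation panels.

Emulates the data structure a pooled sex-marker screen assumes for an XX/XY
plant: a shared autosomal background, an X region present in both sexes, and
a hemizygous Y male-specific region (MSR) present only in males. Pools of
150 bp paired-end reads are drawn from haploid reference sets; hemizygous
sequences carry a dosage weight of 0.5 so the male pool shows the expected
half depth over the MSR. Validation panels mirror the presence/absence
structure of a dominant PCR marker scored on known-sex individuals, with
configurable male dropout and female leakage.

All simulators are deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import Read, ReadPair, revcomp

_BASES = np.frombuffer(b"ACGT", dtype="S1")

#: sequence ids used for the simulated reference sets
AUTOSOME_ID = "autosome"
X_ID = "x_region"
Y_GAMETOLOG_ID = "y_gametolog"
MSR_ID = "y_msr"

DEFAULT_QUALITY = 37  # constant Phred score written unless 3' degradation is requested


@dataclass(frozen=True)
class GenomeModel:
    """Sizes and divergence of the simulated female (XX) / male (XY) genomes.

    ``divergence_xy`` is the fraction of X-region sites substituted in the
    male's Y-borne gametolog copy; at 0.0 (default) the male reference set is
    exactly the female set plus the independently generated Y-MSR.
    """

    autosome_length: int = 100_000
    x_region_length: int = 20_000
    y_msr_length: int = 10_000
    divergence_xy: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.autosome_length, self.x_region_length, self.y_msr_length) < 0:
            raise ValueError("genome lengths must be >= 0")
        if self.autosome_length + self.x_region_length + self.y_msr_length <= 0:
            raise ValueError("total genome length must be positive")
        if not 0.0 <= self.divergence_xy <= 1.0:
            raise ValueError("divergence_xy must be in [0, 1]")


@dataclass(frozen=True)
class ReadSimConfig:
    """Paired-end Illumina-like read simulation parameters.

    With ``circular`` (the default) fragments are drawn as if each template
    were circular, giving uniform coverage: the short synthetic contigs stand
    in for the interior of a much larger genome, and the steep
    orientation-specific depth ramps at linear contig ends are an artifact of
    the toy scale, not a feature of the pooled data being emulated. Reads are
    then exact substrings of the circularized template; a small fraction
    spans the wrap junction. ``circular=False`` confines fragments to the
    linear sequence.
    """

    read_length: int = 150
    fragment_mean: int = 350
    fragment_sd: int = 50
    coverage: float = 30.0
    error_rate: float = 0.0
    seed: int = 0
    circular: bool = True
    degrade_three_prime: bool = False  # write a falling 3' quality ramp to exercise trimming

    def __post_init__(self) -> None:
        if self.read_length > self.fragment_mean:
            raise ValueError("read_length must be <= fragment_mean")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must be in [0, 1)")


@dataclass(frozen=True)
class PanelSpec:
    """Composition and noise of a marker-validation panel.

    ``male_dropout`` is the probability that a male individual lacks the
    marker site (the dominant marker's false-negative mode); ``female_leakage``
    the probability that a female carries it (false positive).
    """

    n_males: int = 45
    n_females: int = 52
    male_dropout: float = 0.0
    female_leakage: float = 0.0
    seed: int = 0
    subpopulation: str = "F1"

    def __post_init__(self) -> None:
        if self.n_males < 0 or self.n_females < 0:
            raise ValueError("panel counts must be >= 0")
        for p in (self.male_dropout, self.female_leakage):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")


@dataclass
class SimulatedGenomes:
    """Female and male haploid reference sets plus per-sequence pool dosages."""

    female: list[tuple[str, str]]
    male: list[tuple[str, str]]
    female_weights: dict[str, float] = field(default_factory=dict)
    male_weights: dict[str, float] = field(default_factory=dict)

    def male_sequence(self, name: str) -> str:
        return dict(self.male)[name]


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    if length == 0:
        return ""
    return rng.choice(_BASES, size=length).tobytes().decode()


def _diverge(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Substitute a ``rate`` fraction of sites with a different random base."""
    if rate == 0.0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    n_sub = int(round(rate * len(seq)))
    sites = rng.choice(len(seq), size=n_sub, replace=False)
    for i in sites:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


def simulate_genomes(model: GenomeModel) -> SimulatedGenomes:
    """Generate the female {autosome, X} and male {autosome, X, [Y-gametolog,] Y-MSR} sets.

    Sequences are uniform i.i.d. A/C/G/T, so the independently drawn Y-MSR
    shares no long exact window with the female genome except with vanishing
    probability. Hemizygous male sequences (Y-MSR and, when divergence_xy > 0,
    the Y gametolog) get dosage weight 0.5.
    """
    rng = np.random.default_rng(model.seed)
    autosome = _random_sequence(rng, model.autosome_length)
    x_region = _random_sequence(rng, model.x_region_length)
    y_msr = _random_sequence(rng, model.y_msr_length)

    female = [(AUTOSOME_ID, autosome), (X_ID, x_region)]
    male = [(AUTOSOME_ID, autosome), (X_ID, x_region)]
    female_w = {AUTOSOME_ID: 1.0, X_ID: 1.0}
    male_w = {AUTOSOME_ID: 1.0, X_ID: 1.0}
    if model.divergence_xy > 0 and model.x_region_length > 0:
        male.append((Y_GAMETOLOG_ID, _diverge(rng, x_region, model.divergence_xy)))
        male_w[Y_GAMETOLOG_ID] = 0.5
        male_w[X_ID] = 0.5  # the male carries one X, one Y gametolog
    if model.y_msr_length > 0:
        male.append((MSR_ID, y_msr))
        male_w[MSR_ID] = 0.5

    female = [(n, s) for n, s in female if s]
    male = [(n, s) for n, s in male if s]
    return SimulatedGenomes(female, male, female_w, male_w)


def _read_name(prefix: str, index: int, seq_id: str, start: int, end: int, strand: str) -> str:
    return f"{prefix}{index:07d}|{seq_id}|{start}|{end}|{strand}"


def parse_read_origin(name: str) -> tuple[str, int, int, str]:
    """Recover (source sequence id, fragment start, fragment end, strand) from a read name."""
    _, seq_id, start, end, strand = name.split("|")
    return seq_id, int(start), int(end), strand


def simulate_pool_reads(
    genomes: list[tuple[str, str]],
    cfg: ReadSimConfig,
    weights: dict[str, float] | None = None,
    name_prefix: str = "read",
) -> list[ReadPair]:
    """Draw paired-end reads from a haploid reference set.

    The pair count is ``round(coverage * sum(w_i * len_i) / (2 * read_length))``
    so that each sequence reaches ``coverage * weight`` expected depth.
    Fragment lengths are normal(fragment_mean, fragment_sd) truncated below at
    read_length; fragments are oriented on either strand with equal
    probability. Read names encode the true fragment origin.
    """
    if not genomes:
        raise ValueError("genome set is empty")
    weights = weights or {}
    eligible = [(n, s) for n, s in genomes if len(s) >= cfg.read_length]
    if not eligible:
        raise ValueError(
            f"read_length {cfg.read_length} exceeds every sequence length"
        )
    rng = np.random.default_rng(cfg.seed)
    w = np.array([weights.get(n, 1.0) * len(s) for n, s in eligible], dtype=float)
    total_weighted = float(w.sum())
    n_pairs = int(round(cfg.coverage * total_weighted / (2 * cfg.read_length)))
    probs = w / total_weighted

    pairs: list[ReadPair] = []
    rl = cfg.read_length
    for i in range(n_pairs):
        idx = rng.choice(len(eligible), p=probs)
        seq_id, seq = eligible[idx]
        frag_len = int(round(rng.normal(cfg.fragment_mean, cfg.fragment_sd)))
        frag_len = max(rl, min(frag_len, len(seq)))
        if cfg.circular:
            start = int(rng.integers(0, len(seq)))
            frag = (seq + seq)[start : start + frag_len]
        else:
            start = int(rng.integers(0, len(seq) - frag_len + 1))
            frag = seq[start : start + frag_len]
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            frag = revcomp(frag)
        r1_seq = _mutate(rng, frag[:rl], cfg.error_rate)
        r2_seq = _mutate(rng, revcomp(frag[-rl:]), cfg.error_rate)
        name = _read_name(name_prefix, i, seq_id, start, start + frag_len, strand)
        q1 = _quality(rng, rl, cfg)
        q2 = _quality(rng, rl, cfg)
        pairs.append((Read(name, r1_seq, q1), Read(name, r2_seq, q2)))
    return pairs


def _mutate(rng: np.random.Generator, seq: str, error_rate: float) -> str:
    if error_rate == 0.0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(seq)) < error_rate)[0]
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


def _quality(rng: np.random.Generator, length: int, cfg: ReadSimConfig) -> str:
    if not cfg.degrade_three_prime:
        return chr(DEFAULT_QUALITY + 33) * length
    # linear ramp from Q37 down to ~Q2 over the final third of the read
    ramp_start = (2 * length) // 3
    vals = np.full(length, DEFAULT_QUALITY)
    tail = length - ramp_start
    vals[ramp_start:] = np.linspace(DEFAULT_QUALITY, 2, tail).round().astype(int)
    return "".join(chr(int(v) + 33) for v in vals)


def simulate_panel(
    marker_template: str,
    background: str,
    spec: PanelSpec,
) -> tuple[dict[str, list[tuple[str, str]]], pd.DataFrame]:
    """Build per-individual template sets and the matching truth table.

    Every individual carries the background sequence; marker carriers
    additionally carry the marker template. Males carry with probability
    1 - male_dropout, females with probability female_leakage.

    Returns (templates by individual id, truth DataFrame with columns
    individual_id / sex / subpopulation / carries_marker).
    """
    if not marker_template:
        raise ValueError("marker_template must be nonempty")
    rng = np.random.default_rng(spec.seed)
    templates: dict[str, list[tuple[str, str]]] = {}
    rows = []
    for sex, count, p_carry in (
        ("male", spec.n_males, 1.0 - spec.male_dropout),
        ("female", spec.n_females, spec.female_leakage),
    ):
        for i in range(count):
            ind = f"{spec.subpopulation}_{sex[0].upper()}{i + 1:03d}"
            carries = bool(rng.random() < p_carry)
            seqs = [("background", background)] if background else []
            if carries:
                seqs.append(("marker", marker_template))
            templates[ind] = seqs
            rows.append(
                {
                    "individual_id": ind,
                    "sex": sex,
                    "subpopulation": spec.subpopulation,
                    "carries_marker": carries,
                }
            )
    return templates, pd.DataFrame(rows, columns=["individual_id", "sex", "subpopulation", "carries_marker"])
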
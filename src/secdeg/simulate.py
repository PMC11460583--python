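"""Ground-truth-annotated synthetic PSM tables.

The generator emulates the structure of a 21-fraction SEC / TMT-11 experiment:
three conditions (LPS priming alone ``L``, LPS + nigericin ``L+N``, LPS + VbP
``L+V``) x three replicates per 11-plex set, one reference channel carrying a
pre-SEC pooled mix, one empty channel, spiked iRT standards, isolation-purity
draws, decoy/contaminant records and missing reporter cells.

Elution is modelled as a log2-additive Gaussian bump over fractions; proteins
needing two peaks (e.g. a treatment-specific low-MW accumulation) are mixtures
of two Gaussians.  For each planted cleavage event the two semi-tryptic
peptides flanking the site are emitted; the C-terminal fragment follows the
event's retained/released behaviour (a released fragment elutes at a later,
lower-MW target fraction in every condition) while the N-terminal fragment
co-elutes with the parent.  Reporter intensity for sample ``s`` in fraction
``f`` is ``2 ** (baseline + bump(f) + delta_condition(s) + eps)`` with
``eps ~ Normal(0, sigma_noise)``; the reference channel carries the pre-SEC
pooled (fraction-averaged, sample-averaged) signal so that log2 ratios stay
centred near zero while preserving the elution shape.

Every scripted scenario of the source system is represented: an ASC-like
condition-specific complex shift, an IL-1beta-like low-MW accumulation under
treatment, retained caspase-like (P1 = Asp) cleavages and released cleavage
products, plus protease families planted at high- and low-MW fractions for
the protease-profiling stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd
from pyteomics import parser as _pyt_parser

from .design import CONDITIONS, SAMPLES, PlexDesign, condition_of
from .errors import ConfigError
from .io import ProteomeDb, write_fasta, write_merops, write_psm_table

#: residues used for random sequence segments (everything but K/R)
_SEGMENT_RESIDUES = "ACDEFGHILMNPQSTVWY"
_P1_ALTERNATIVES = "AEGSV"  # non-Asp P1 residues for planted cleavages

IRT_ACCESSION = "iRT_standard"
IRT_PEPTIDES = ("LGGNEQVTR", "GAGSSEPVTGLDAK", "VEATFGVDESNAK", "YILAGVENSK")

#: planted peak fraction per protease family (high MW = early fraction)
PROTEASE_FAMILY_MU = {
    "ADAM": 4.0,
    "DPP": 5.0,
    "proteasome": 10.0,
    "caspase": 12.0,
    "MMP": 19.0,
}


@dataclass(frozen=True)
class SimConfig:
    """Tunable generator parameters (defaults are the study conditions)."""

    n_fractions: int = 21
    n_proteins: int = 40
    n_cleavage_events: int = 12
    n_proteases_per_family: int = 2
    protein_length: tuple[int, int] = (240, 400)
    segment_length: tuple[int, int] = (6, 24)
    baseline_log2: tuple[float, float] = (10.0, 1.0)  # mean, sd
    amplitude_log2: float = 6.0
    sigma_elution: float = 1.5
    mu_range: tuple[float, float] = (4.0, 19.0)
    delta_log2: float = 2.0
    release_fraction: float = 0.5
    release_shift: tuple[float, float] = (6.0, 11.0)
    frac_p1_asp: float = 0.8
    fragment_drop_log2: float = 2.0
    sigma_noise: float = 0.3
    missingness: float = 0.05
    low_purity_rate: float = 0.1
    decoy_rate: float = 0.02
    contaminant_rate: float = 0.01
    detect_margin_log2: float = 1.2
    peptide_length: tuple[int, int] = (7, 30)
    missed_cleavages: int = 1
    cleave_before_pro: bool = True
    irt_per_fraction: int = 3
    irt_log2: float = 12.0
    purity_ok: tuple[float, float] = (0.55, 0.995)
    purity_low: tuple[float, float] = (0.05, 0.5)
    empty_noise: float = 1.0

    def __post_init__(self) -> None:
        if self.n_fractions < 2:
            raise ConfigError(f"need at least 2 fractions, got {self.n_fractions}")
        if not 0 <= self.missingness < 1:
            raise ConfigError("missingness must lie in [0, 1)")
        if self.sigma_noise < 0:
            raise ConfigError("sigma_noise must be non-negative")

    @classmethod
    def from_dict(cls, overrides: dict) -> "SimConfig":
        known = {f.name for f in fields(cls)}
        bad = set(overrides) - known
        if bad:
            raise ConfigError(f"unknown simulation option(s): {sorted(bad)}")
        coerced = {
            k: tuple(v) if isinstance(v, list) else v for k, v in overrides.items()
        }
        return cls(**coerced)


@dataclass(frozen=True)
class Component:
    """One Gaussian elution component: peak fraction, width, log2 amplitude."""

    mu: float
    sigma: float
    amplitude: float


def _shape_log2(
    components: tuple[Component, ...], fractions: np.ndarray
) -> np.ndarray:
    """log2 of the summed linear contributions of all components."""
    total = np.zeros_like(fractions, dtype=float)
    for c in components:
        total += np.exp2(c.amplitude * np.exp(-((fractions - c.mu) ** 2) / (2 * c.sigma**2)))
    return np.log2(total)


@dataclass
class ProteinTruth:
    accession: str
    gene: str
    sequence: str
    baseline: float
    components: dict[str, tuple[Component, ...]]  # per condition
    protease_family: str | None = None

    def primary_mu(self, condition: str) -> float:
        return self.components[condition][0].mu


@dataclass
class CleavageEvent:
    event_id: str
    accession: str
    cleavage_pos: int  # 1-based position of the P1 residue
    p1: str
    behavior: str  # "retained" | "released"
    mu_release: float | None
    delta: dict[str, float]  # per-condition log2 effect on the semi peptides


@dataclass
class PeptideTruth:
    """One quantifiable peptide with its designed elution and effect."""

    peptide: str
    accession: str
    start_pos: int
    kind: str  # "tryptic" | "semi_N" | "semi_C"
    event_id: str | None
    cleavage_pos: int | None
    p1: str | None
    behavior: str | None  # retained / released for semi peptides
    baseline: float
    components: dict[str, tuple[Component, ...]]
    delta: dict[str, float]

    def shape_log2(self, condition: str, fractions: np.ndarray) -> np.ndarray:
        return _shape_log2(self.components[condition], fractions)

    def linear_intensity(self, condition: str, fractions: np.ndarray) -> np.ndarray:
        return np.exp2(
            self.baseline + self.delta[condition] + self.shape_log2(condition, fractions)
        )

    def reference_linear(self, n_fractions: int) -> float:
        """Pre-SEC pooled signal: mean over conditions of the fraction-averaged
        linear intensity (each condition contributes equally)."""
        grid = np.arange(1, n_fractions + 1, dtype=float)
        return float(
            np.mean([self.linear_intensity(c, grid).mean() for c in CONDITIONS])
        )

    def expected_normalized(
        self, condition: str, fractions: np.ndarray, n_fractions: int
    ) -> np.ndarray:
        """Designed log2(sample / reference) ratio in the zero-noise limit."""
        return np.log2(self.linear_intensity(condition, fractions)) - math.log2(
            self.reference_linear(n_fractions)
        )

    def peak_fraction(self, condition: str, n_fractions: int) -> int:
        grid = np.arange(1, n_fractions + 1, dtype=float)
        return int(grid[np.argmax(self.shape_log2(condition, grid))])


@dataclass
class GroundTruth:
    config: SimConfig
    seed: int
    proteins: list[ProteinTruth]
    events: list[CleavageEvent]
    _catalog: list[PeptideTruth] | None = field(default=None, repr=False)

    def proteome(self) -> ProteomeDb:
        db = ProteomeDb()
        for p in self.proteins:
            db.add(p.accession, p.sequence, p.gene)
        return db

    def merops_table(self) -> pd.DataFrame:
        rows = [
            {
                "accession": p.accession,
                "family": p.protease_family,
                "gene": p.gene,
                "is_protease": True,
            }
            for p in self.proteins
            if p.protease_family
        ]
        return pd.DataFrame(
            rows, columns=["accession", "family", "gene", "is_protease"]
        ).set_index("accession")

    def peptide_catalog(self) -> list[PeptideTruth]:
        if self._catalog is None:
            self._catalog = _build_catalog(self)
        return self._catalog

    def peptides_frame(self) -> pd.DataFrame:
        """Ground-truth label table for the emitted quantifiable peptides."""
        cfg = self.config
        rows = []
        for pt in self.peptide_catalog():
            row = {
                "peptide": pt.peptide,
                "accession": pt.accession,
                "start_pos": pt.start_pos,
                "kind": pt.kind,
                "event_id": pt.event_id or "",
                "cleavage_pos": pt.cleavage_pos if pt.cleavage_pos else "",
                "p1": pt.p1 or "",
                "behavior": pt.behavior or "",
            }
            for cond in CONDITIONS:
                row[f"peak_{cond}"] = pt.peak_fraction(cond, cfg.n_fractions)
                row[f"delta_{cond}"] = pt.delta[cond]
            rows.append(row)
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# sequence construction and digestion


def _random_sequence(rng: np.random.Generator, cfg: SimConfig) -> str:
    """Random protein: Met start, then segments ending in K/R so that tryptic
    peptides mostly fall in the searchable length range."""
    lo, hi = cfg.protein_length
    target = int(rng.integers(lo, hi + 1))
    parts = ["M"]
    length = 1
    while length < target:
        seg_len = int(rng.integers(*cfg.segment_length))
        seg = "".join(rng.choice(list(_SEGMENT_RESIDUES), size=seg_len))
        cut = str(rng.choice(["K", "R"]))
        parts.append(seg + cut)
        length += seg_len + 1
    return "".join(parts)


def digest(
    sequence: str,
    missed_cleavages: int = 1,
    length_range: tuple[int, int] = (7, 30),
    cleave_before_pro: bool = True,
) -> list[tuple[int, str]]:
    """In-silico tryptic digestion: (1-based start, peptide) pairs.

    Cleaves after K/R (including before proline by default, matching a
    strict-trypsin search); up to ``missed_cleavages`` missed cleavages,
    peptide length restricted to ``length_range``.
    """
    rule = r"[KR]" if cleave_before_pro else _pyt_parser.expasy_rules["trypsin"]
    lo, hi = length_range
    seen: set[tuple[int, str]] = set()
    out: list[tuple[int, str]] = []
    for start0, pep in _pyt_parser.icleave(
        sequence, rule, missed_cleavages=missed_cleavages,
        min_length=lo, max_length=hi,
    ):
        key = (start0 + 1, pep)
        if key not in seen:
            seen.add(key)
            out.append(key)
    return sorted(out)


def _cut_positions(sequence: str) -> list[int]:
    """1-based positions of K/R residues (tryptic cut sites are after these)."""
    return [i + 1 for i, aa in enumerate(sequence) if aa in "KR"]


def _candidate_cleavage_positions(sequence: str, cfg: SimConfig) -> list[int]:
    """Positions usable as a planted P1: both flanking semi peptides must fall
    in the searchable length range and full P5-P5' windows must exist."""
    lo, hi = cfg.peptide_length
    n = len(sequence)
    cuts = _cut_positions(sequence)
    candidates = []
    for p in range(5, n - 4):
        if sequence[p - 1] in "KR":
            continue
        prev_cut = max((c for c in cuts if c < p), default=0)
        next_cut = min((c for c in cuts if c > p), default=n)
        len_c = p - prev_cut        # N-terminal (semi_C) fragment
        len_n = next_cut - p        # C-terminal (semi_N) fragment
        if lo <= len_c <= hi and lo <= len_n <= hi:
            candidates.append(p)
    return candidates


# ---------------------------------------------------------------------------
# ground truth


def generate_ground_truth(config: SimConfig | None = None, seed: int = 0) -> GroundTruth:
    """Draw the designed proteome, elution profiles and cleavage events.

    Deterministic for a fixed seed.  Always includes (when the protein budget
    allows) one ASC-like condition-specific complex shift, one IL-1beta-like
    treatment-specific low-MW accumulation, one retained P1-Asp cleavage and
    one released cleavage whose product elutes at a later fraction than its
    parent.
    """
    cfg = config or SimConfig()
    rng = np.random.default_rng(seed)
    nf = cfg.n_fractions
    sig = cfg.sigma_elution
    amp = cfg.amplitude_log2

    sequences = [_random_sequence(rng, cfg) for _ in range(cfg.n_proteins)]
    baselines = rng.normal(*cfg.baseline_log2, size=cfg.n_proteins)
    mus = rng.uniform(*cfg.mu_range, size=cfg.n_proteins)
    mus = np.clip(mus, 1.0, float(nf))

    families: dict[int, str] = {}
    if cfg.n_proteases_per_family > 0:
        fam_names = list(PROTEASE_FAMILY_MU)
        n_prot = min(
            len(fam_names) * cfg.n_proteases_per_family, max(cfg.n_proteins - 4, 0)
        )
        first = cfg.n_proteins - n_prot
        for j in range(n_prot):
            idx = first + j
            fam = fam_names[j % len(fam_names)]
            families[idx] = fam
            mus[idx] = min(PROTEASE_FAMILY_MU[fam], float(nf))

    proteins: list[ProteinTruth] = []
    for i, seq in enumerate(sequences):
        comps = {
            c: (Component(float(mus[i]), sig, amp),) for c in CONDITIONS
        }
        proteins.append(
            ProteinTruth(
                accession=f"PROT{i:04d}",
                gene=f"GENE{i}",
                sequence=seq,
                baseline=float(baselines[i]),
                components=comps,
                protease_family=families.get(i),
            )
        )

    # scripted profile scenarios (need a few unscripted, non-protease proteins)
    scriptable = [i for i in range(cfg.n_proteins) if i not in families]
    if len(scriptable) >= 4:
        asc, il1b, rock_host = scriptable[0], scriptable[1], scriptable[2]
        late = min(19.0, float(nf))
        early = min(6.0, float(nf) / 2)
        # ASC-like: complex shift to earlier (higher-MW) fractions upon treatment
        proteins[asc].components = {
            "L": (Component(min(16.0, float(nf)), sig, amp),),
            "L+N": (Component(early, sig, amp),),
            "L+V": (Component(early, sig, amp),),
        }
        # IL-1beta-like: extra low-MW (late) component under treatment only
        mid = Component(min(10.0, float(nf) / 2), sig, amp)
        proteins[il1b].components = {
            "L": (mid,),
            "L+N": (mid, Component(late, sig, amp)),
            "L+V": (mid, Component(late, sig, amp)),
        }
        # Rock1-like host for the scripted released event: peak at fraction 8
        rock_mu = min(8.0, float(nf) / 2)
        proteins[rock_host].components = {
            c: (Component(rock_mu, sig, amp),) for c in CONDITIONS
        }

    events: list[CleavageEvent] = []
    if cfg.n_cleavage_events > 0:
        host_order = scriptable[2:] + scriptable[:2] or list(range(cfg.n_proteins))
        used: dict[int, list[int]] = {}
        delta = {
            "L": 0.0, "L+N": float(cfg.delta_log2), "L+V": float(cfg.delta_log2)
        }
        k = 0
        hosts_cycle = 0
        while k < cfg.n_cleavage_events:
            idx = host_order[hosts_cycle % len(host_order)]
            hosts_cycle += 1
            if hosts_cycle > cfg.n_cleavage_events * 4 + len(host_order):
                raise ConfigError(
                    "could not place all requested cleavage events; "
                    "increase n_proteins or protein_length"
                )
            prot = proteins[idx]
            cands = [
                p
                for p in _candidate_cleavage_positions(prot.sequence, cfg)
                if all(abs(p - q) >= 12 for q in used.get(idx, []))
            ]
            if not cands:
                continue
            p = int(cands[int(rng.integers(len(cands)))])
            used.setdefault(idx, []).append(p)
            if k == 0:
                behavior, p1 = "released", "D"  # scripted Rock1-like event
            elif k == 1:
                behavior, p1 = "retained", "D"  # scripted retained P1-Asp event
            else:
                behavior = (
                    "released" if rng.random() < cfg.release_fraction else "retained"
                )
                p1 = (
                    "D"
                    if rng.random() < cfg.frac_p1_asp
                    else str(rng.choice(list(_P1_ALTERNATIVES)))
                )
            mu_rel = None
            if behavior == "released":
                shift = float(rng.uniform(*cfg.release_shift))
                mu_rel = min(float(nf), prot.primary_mu("L") + shift)
                if mu_rel <= prot.primary_mu("L"):
                    behavior, mu_rel = "retained", None
            # plant the P1 residue into the sequence
            seq = prot.sequence
            prot.sequence = seq[: p - 1] + p1 + seq[p:]
            events.append(
                CleavageEvent(
                    event_id=f"EV{k:04d}",
                    accession=prot.accession,
                    cleavage_pos=p,
                    p1=p1,
                    behavior=behavior,
                    mu_release=mu_rel,
                    delta=dict(delta),
                )
            )
            k += 1

    return GroundTruth(config=cfg, seed=seed, proteins=proteins, events=events)


def _build_catalog(truth: GroundTruth) -> list[PeptideTruth]:
    cfg = truth.config
    by_acc = {p.accession: p for p in truth.proteins}
    catalog: list[PeptideTruth] = []
    zero_delta = {c: 0.0 for c in CONDITIONS}
    for prot in truth.proteins:
        for start, pep in digest(
            prot.sequence,
            cfg.missed_cleavages,
            cfg.peptide_length,
            cfg.cleave_before_pro,
        ):
            catalog.append(
                PeptideTruth(
                    peptide=pep,
                    accession=prot.accession,
                    start_pos=start,
                    kind="tryptic",
                    event_id=None,
                    cleavage_pos=None,
                    p1=None,
                    behavior=None,
                    baseline=prot.baseline,
                    components=prot.components,
                    delta=dict(zero_delta),
                )
            )
    for ev in truth.events:
        prot = by_acc[ev.accession]
        seq = prot.sequence
        cuts = _cut_positions(seq)
        p = ev.cleavage_pos
        prev_cut = max((c for c in cuts if c < p), default=0)
        next_cut = min((c for c in cuts if c > p), default=len(seq))
        frag_base = prot.baseline - cfg.fragment_drop_log2
        retained_comps = prot.components
        if ev.behavior == "released":
            released_comps = {
                c: (Component(float(ev.mu_release), cfg.sigma_elution,
                              cfg.amplitude_log2),)
                for c in CONDITIONS
            }
        else:
            released_comps = retained_comps
        # N-terminal fragment (semi_C): tryptic N-terminus, cleaved C-terminus;
        # always co-elutes with the parent protein.
        catalog.append(
            PeptideTruth(
                peptide=seq[prev_cut:p],
                accession=ev.accession,
                start_pos=prev_cut + 1,
                kind="semi_C",
                event_id=ev.event_id,
                cleavage_pos=p,
                p1=ev.p1,
                behavior="retained",
                baseline=frag_base,
                components=retained_comps,
                delta=dict(ev.delta),
            )
        )
        # C-terminal fragment (semi_N): cleaved N-terminus, tryptic C-terminus;
        # follows the event's retained/released behaviour.
        catalog.append(
            PeptideTruth(
                peptide=seq[p:next_cut],
                accession=ev.accession,
                start_pos=p + 1,
                kind="semi_N",
                event_id=ev.event_id,
                cleavage_pos=p,
                p1=ev.p1,
                behavior=ev.behavior,
                baseline=frag_base,
                components=released_comps,
                delta=dict(ev.delta),
            )
        )
    return catalog


# ---------------------------------------------------------------------------
# PSM simulation


@dataclass
class SimulatedData:
    tables: dict[int, pd.DataFrame]  # fraction -> PSM frame (dialect columns)
    flags: pd.DataFrame  # per-PSM ground-truth flags


def simulate_psm_tables(
    truth: GroundTruth, designs: dict[int, PlexDesign], seed: int = 0
) -> SimulatedData:
    """Emit one PSM table per fraction plus a per-PSM ground-truth flag table.

    Deterministic for fixed (truth, designs, seed).  Every emitted PSM's
    peptide occurs verbatim in its protein at its stated start position.
    """
    cfg = truth.config
    rng = np.random.default_rng(seed)
    nf = cfg.n_fractions
    grid = np.arange(1, nf + 1, dtype=float)
    sample_conditions = [condition_of(s) for s in SAMPLES]
    by_acc = {p.accession: p for p in truth.proteins}

    # per-fraction row accumulators (dialect columns)
    rows: dict[int, list[dict]] = {f: [] for f in designs}
    flag_rows: list[dict] = []
    counters = {f: 0 for f in designs}

    def _spectrum(f: int) -> str:
        counters[f] += 1
        return f"F{f:02d}.{counters[f]:05d}"

    def _emit(
        f: int,
        peptide: str,
        accession: str,
        prev_aa: str,
        next_aa: str,
        start: int,
        sample_lin: np.ndarray,
        ref_lin: float,
        kind: str,
        nterm_label: bool = True,
    ) -> None:
        design = designs[f]
        low_purity = bool(rng.random() < cfg.low_purity_rate) and kind == "quant"
        purity = float(
            rng.uniform(*(cfg.purity_low if low_purity else cfg.purity_ok))
        )
        if cfg.missingness > 0 and kind == "quant":
            drop = rng.random(len(sample_lin)) < cfg.missingness
            sample_lin = np.where(drop, 0.0, sample_lin)
        sample_map = dict(zip(SAMPLES, sample_lin))
        spectrum = _spectrum(f)
        row = {
            "spectrum": spectrum,
            "peptide": peptide,
            "accession": accession,
            "prev_aa": prev_aa,
            "next_aa": next_aa,
            "start_pos": start,
            "purity": purity,
            "has_nterm_label": nterm_label,
        }
        for channel, role in design.roles.items():
            if role.kind == "sample":
                row[channel] = sample_map[role.sample]
            elif role.kind == "reference":
                row[channel] = ref_lin
            else:
                row[channel] = float(rng.uniform(0.0, cfg.empty_noise))
        rows[f].append(row)
        flag_rows.append(
            {
                "spectrum": spectrum,
                "fraction_id": f,
                "peptide": peptide,
                "accession": accession,
                "kind": kind,
                "is_low_purity": low_purity,
            }
        )

    for pt in truth.peptide_catalog():
        seq = by_acc[pt.accession].sequence
        end = pt.start_pos + len(pt.peptide) - 1
        prev_aa = seq[pt.start_pos - 2] if pt.start_pos > 1 else "-"
        next_aa = seq[end] if end < len(seq) else "-"
        shapes = {c: pt.shape_log2(c, grid) for c in CONDITIONS}
        detected = np.flatnonzero(
            np.max(np.vstack(list(shapes.values())), axis=0) >= cfg.detect_margin_log2
        )
        if detected.size == 0:
            continue
        ref_lin = pt.reference_linear(nf)
        for fi in detected:
            f = int(grid[fi])
            if f not in designs:
                continue
            eps = (
                rng.normal(0.0, cfg.sigma_noise, size=len(SAMPLES) + 1)
                if cfg.sigma_noise > 0
                else np.zeros(len(SAMPLES) + 1)
            )
            sample_lin = np.array(
                [
                    2.0
                    ** (
                        pt.baseline
                        + pt.delta[c]
                        + shapes[c][fi]
                        + eps[k]
                    )
                    for k, c in enumerate(sample_conditions)
                ]
            )
            _emit(
                f, pt.peptide, pt.accession, prev_aa, next_aa, pt.start_pos,
                sample_lin, ref_lin * 2.0 ** eps[-1], "quant",
            )

    # spiked iRT standards: equal expected intensity in all non-empty channels
    for f in designs:
        for j in range(cfg.irt_per_fraction):
            pep = IRT_PEPTIDES[j % len(IRT_PEPTIDES)]
            eps = (
                rng.normal(0.0, cfg.sigma_noise, size=len(SAMPLES) + 1)
                if cfg.sigma_noise > 0
                else np.zeros(len(SAMPLES) + 1)
            )
            sample_lin = 2.0 ** (cfg.irt_log2 + eps[: len(SAMPLES)])
            _emit(
                f, pep, IRT_ACCESSION, "-", "-", 1,
                sample_lin, float(2.0 ** (cfg.irt_log2 + eps[-1])), "irt",
            )

    # decoys and contaminants
    n_real = {f: len(rows[f]) for f in designs}
    for f in designs:
        for kind, prefix, rate in (
            ("decoy", "rev_", cfg.decoy_rate),
            ("contaminant", "contam_", cfg.contaminant_rate),
        ):
            n = int(rng.binomial(max(n_real[f], 1), rate)) if rate > 0 else 0
            for _ in range(n):
                pep = "".join(rng.choice(list(_SEGMENT_RESIDUES), size=11)) + "K"
                lin = rng.uniform(50.0, 500.0, size=len(SAMPLES))
                _emit(
                    f, pep, f"{prefix}PROT9999", "K", "A", 1,
                    lin, float(rng.uniform(50.0, 500.0)), kind,
                )

    cfg_channels = None
    tables: dict[int, pd.DataFrame] = {}
    for f, design in designs.items():
        cfg_channels = list(design.channels)
        columns = [
            "spectrum", "peptide", "accession", "prev_aa", "next_aa",
            "start_pos", "purity", "has_nterm_label", *cfg_channels,
        ]
        frame = pd.DataFrame(rows[f], columns=columns)
        frame["is_decoy"] = frame["accession"].str.startswith("rev_")
        frame["is_contaminant"] = frame["accession"].str.startswith("contam_")
        frame["is_irt"] = frame["accession"].str.startswith("iRT_")
        frame["fraction_id"] = f
        tables[f] = frame
    flags = pd.DataFrame(
        flag_rows,
        columns=[
            "spectrum", "fraction_id", "peptide", "accession", "kind",
            "is_low_purity",
        ],
    )
    return SimulatedData(tables=tables, flags=flags)


def write_simulation(
    sim: SimulatedData,
    truth: GroundTruth,
    designs: dict[int, PlexDesign],
    out_dir,
) -> None:
    """Write the full fixture set: per-fraction PSM TSVs, design, FASTA,
    protease annotation and the ground-truth label tables."""
    from pathlib import Path

    from .design import write_design

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for f, frame in sim.tables.items():
        write_psm_table(frame, designs[f], out / f"psm_fraction{f:02d}.tsv")
    write_design(designs, out / "design.tsv")
    write_fasta(truth.proteome(), out / "proteome.fasta")
    write_merops(truth.merops_table(), out / "merops.tsv")
    truth.peptides_frame().to_csv(out / "truth_peptides.tsv", sep="\t", index=False)
    sim.flags.to_csv(out / "truth_psm_flags.tsv", sep="\t", index=False)
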
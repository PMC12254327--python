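"""In-silico MM-seq library generator.

Emulates the molecular workflow at the level the downstream pipeline sees:

  * duplex molecules are drawn from reference contigs (optionally spike-in
    analogs of fully unmethylated lambda and methylated pUC19 dilutions),
    carry per-CpG methylation states and planted variants, and receive a
    fixed-pool UMI at each end;
  * a protective copy-synthesis step produces ``2**c - 1`` protected strands
    per original strand (exponential doubling over ``c`` cycles; one cycle is
    typical for genomic DNA, three for cell-free DNA);
  * enzymatic conversion then deaminates cytosines: on original strands an
    unmethylated C reads as T with probability ``conversion_sensitivity`` and
    a methylated C with ``1 - conversion_specificity``; on protected strands
    every C (the analog) reads as T with ``1 - analog_resistance``. UMI bases
    are unmodified cytosines and convert like unmethylated genomic Cs;
  * strands are lost with probability ``1 - strand_survival`` and PCR emits
    extra duplicate copies at rate ``pcr_duplicate_rate``.

Every emitted read pair / fragment has exactly one truth record, so each
pipeline stage can be scored against ground truth.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..core.seqs import revcomp
from ..core.types import (
    CRICK,
    GENET_CRICK_FLAGS,
    GENET_WATSON_FLAGS,
    METH_CRICK_FLAGS,
    METH_WATSON_FLAGS,
    WATSON,
    AlignedFragment,
    Meth,
    ReadPair,
    Stream,
)
from ..core.umi import UMIPool, default_pool

_A, _C, _G, _T = 65, 67, 71, 84

# Standard pUC19 dilution series: fraction of molecules fully CpG-methylated.
PUC19_DILUTIONS = (0.05, 0.02, 0.01, 0.005, 0.002, 0.0)


@dataclass
class ContigSpec:
    length: int
    gc: float = 0.45
    kind: str = "genomic"  # genomic | lambda | puc19
    methylation_level: float = 0.0  # puc19 only: P(molecule fully methylated)
    n_molecules: int = 0


@dataclass
class PlantedVariant:
    contig: str
    position: int
    ref: str
    alt: str
    allele_fraction: float


@dataclass
class ASMEffect:
    """Allele-specific methylation: CpGs near the SNP follow the carried allele."""

    contig: str
    snp_position: int
    beta_ref: float
    beta_alt: float
    window: int = 200


@dataclass
class SimConfig:
    contigs: dict[str, ContigSpec]
    planted_variants: list[PlantedVariant] = field(default_factory=list)
    asm_effects: list[ASMEffect] = field(default_factory=list)
    cpg_beta: dict[tuple[str, int], float] | None = None  # explicit truth overrides
    conversion_sensitivity: float = 0.9989
    conversion_specificity: float = 0.9743
    analog_resistance: float = 0.95
    copy_cycles: int = 1  # 1 for gDNA, 3 for cfDNA
    strand_survival: float = 0.8
    pcr_duplicate_rate: float = 0.1
    fragment_length_min: int = 60  # fragment lengths uniform in [min, max];
    fragment_length: int = 90      # both mates fully cover the molecule
    emit_reads: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name, p in [("conversion_sensitivity", self.conversion_sensitivity),
                        ("conversion_specificity", self.conversion_specificity),
                        ("analog_resistance", self.analog_resistance),
                        ("strand_survival", self.strand_survival),
                        ("pcr_duplicate_rate", self.pcr_duplicate_rate)]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")
        for v in self.planted_variants:
            if not 0.0 <= v.allele_fraction <= 1.0:
                raise ValueError("allele fraction outside [0, 1]")
        if self.copy_cycles < 0:
            raise ValueError("copy_cycles must be >= 0")
        if self.pcr_duplicate_rate >= 1.0:
            raise ValueError("pcr_duplicate_rate must be < 1")

    @property
    def n_protected_per_original(self) -> int:
        return 2 ** self.copy_cycles - 1


def spike_in_contigs(genomic_length: int = 20_000, genomic_molecules: int = 2_000,
                     spike_molecules: int = 300, gc: float = 0.45) -> dict[str, ContigSpec]:
    """A standard contig layout: one genomic contig, a lambda analog, and the
    pUC19 dilution series (5/2/1/0.5/0.2/0 %)."""
    contigs = {
        "chr1": ContigSpec(genomic_length, gc=gc, n_molecules=genomic_molecules),
        "lambda": ContigSpec(3_000, gc=0.5, kind="lambda", n_molecules=spike_molecules),
    }
    for level in PUC19_DILUTIONS:
        name = f"pUC19_{level * 100:g}pct"
        contigs[name] = ContigSpec(1_500, gc=0.5, kind="puc19",
                                   methylation_level=level, n_molecules=spike_molecules)
    return contigs


@dataclass
class TruthRecord:
    name: str
    molecule_id: int
    contig: str
    start: int
    end: int
    strand: str  # WATSON | CRICK (sequencing sense of the strand)
    stream: Stream  # METH for originals, GENET for protected copies
    umi1: str  # true pool UMI in mate-1 position
    umi2: str
    is_duplicate: bool
    variants: tuple[tuple[int, str], ...] = ()


@dataclass
class SimTruth:
    records: dict[str, TruthRecord] = field(default_factory=dict)
    cpg_beta: dict[tuple[str, int], float] = field(default_factory=dict)
    molecule_cpgs: dict[int, dict[int, int]] = field(default_factory=dict)
    variants: list[PlantedVariant] = field(default_factory=list)
    n_strands_total: int = 0
    n_strands_surviving: int = 0
    n_duplicates: int = 0


@dataclass
class SimResult:
    reference: dict[str, str]
    pool: UMIPool
    read_pairs: list[ReadPair]
    fragments: list[AlignedFragment]
    truth: SimTruth


_FLAGS = {
    (Stream.METH, WATSON): METH_WATSON_FLAGS,
    (Stream.METH, CRICK): METH_CRICK_FLAGS,
    (Stream.GENET, WATSON): GENET_WATSON_FLAGS,
    (Stream.GENET, CRICK): GENET_CRICK_FLAGS,
}


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return np.array([_A, _C, _G, _T], dtype=np.uint8)[
        rng.choice(4, size=length, p=probs)]


def _convert_umi(rng: np.random.Generator, umi: str, base: str, prob: float) -> str:
    """Convert each occurrence of ``base`` (C or G) independently with ``prob``."""
    if prob <= 0.0:
        return umi
    to = "T" if base == "C" else "A"
    out = []
    for ch in umi:
        if ch == base and rng.random() < prob:
            out.append(to)
        else:
            out.append(ch)
    return "".join(out)


class LibrarySimulator:
    def __init__(self, config: SimConfig, pool: UMIPool | None = None):
        if not config.contigs:
            raise ValueError("no contigs configured")
        if all(spec.n_molecules == 0 for spec in config.contigs.values()):
            raise ValueError("zero molecules configured")
        self.config = config
        self.pool = pool if pool is not None else default_pool()
        if len(self.pool) == 0:
            raise ValueError("empty UMI pool")
        self.rng = np.random.default_rng(config.seed)

    # ------------------------------------------------------------ reference

    def build_reference(self) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray],
                                       dict[str, np.ndarray]]:
        """Random contigs, their CpG dyad positions and truth betas."""
        cfg = self.config
        arrays: dict[str, np.ndarray] = {}
        cpg_pos: dict[str, np.ndarray] = {}
        cpg_beta: dict[str, np.ndarray] = {}
        for name, spec in cfg.contigs.items():
            arr = _random_sequence(self.rng, spec.length, spec.gc)
            for v in cfg.planted_variants:
                if v.contig == name:
                    arr[v.position] = ord(v.ref)
            arrays[name] = arr
            pos = np.flatnonzero((arr[:-1] == _C) & (arr[1:] == _G))
            cpg_pos[name] = pos
            if spec.kind == "lambda":
                beta = np.zeros(pos.size)
            elif spec.kind == "puc19":
                beta = np.full(pos.size, spec.methylation_level)
            else:
                # bimodal genomic methylation: half lowly, half highly methylated
                low = self.rng.random(pos.size) < 0.5
                beta = np.where(low, self.rng.uniform(0.0, 0.1, pos.size),
                                self.rng.uniform(0.9, 1.0, pos.size))
            if cfg.cpg_beta:
                for i, p in enumerate(pos):
                    override = cfg.cpg_beta.get((name, int(p)))
                    if override is not None:
                        beta[i] = override
            cpg_beta[name] = beta
        return arrays, cpg_pos, cpg_beta

    # ------------------------------------------------------------- strands

    def _observe_strand(self, mol: np.ndarray, start: int, dyad_pos: np.ndarray,
                        dyad_state: np.ndarray, stream: Stream, sense: str):
        """Apply conversion to one strand; return plus-oriented observed bases
        and the observed per-dyad methylation states (METH only)."""
        cfg = self.config
        rng = self.rng
        obs = mol.copy()
        if sense == WATSON:
            idx = np.flatnonzero(obs == _C)
            informative = dyad_pos - start
            meth_c_pos = dyad_pos[dyad_state]  # plus-strand C of methylated dyads
            converted_to = _T
        else:
            idx = np.flatnonzero(obs == _G)
            informative = dyad_pos - start + 1
            meth_c_pos = dyad_pos[dyad_state] + 1  # the G is the minus-strand C
            converted_to = _A
        if stream is Stream.METH:
            probs = np.full(idx.size, cfg.conversion_sensitivity)
            probs[np.isin(idx + start, meth_c_pos)] = 1.0 - cfg.conversion_specificity
        else:
            probs = np.full(idx.size, 1.0 - cfg.analog_resistance)
        if idx.size:
            hit = rng.random(idx.size) < probs
            obs[idx[hit]] = converted_to
        states: dict[int, Meth] = {}
        if stream is Stream.METH:
            base_m = _C if sense == WATSON else _G
            base_u = _T if sense == WATSON else _A
            for p, i in zip(dyad_pos, informative):
                b = obs[i]
                if b == base_m:
                    states[int(p)] = Meth.METHYLATED
                elif b == base_u:
                    states[int(p)] = Meth.UNMETHYLATED
                # any other base (planted variant) is uninformative: skipped
        return obs, states

    # ---------------------------------------------------------------- main

    def run(self) -> SimResult:
        cfg = self.config
        rng = self.rng
        arrays, cpg_pos, cpg_beta = self.build_reference()
        truth = SimTruth(variants=list(cfg.planted_variants))
        for contig, pos in cpg_pos.items():
            for p, b in zip(pos, cpg_beta[contig]):
                truth.cpg_beta[(contig, int(p))] = float(b)

        read_pairs: list[ReadPair] = []
        fragments: list[AlignedFragment] = []
        dup_lambda = (cfg.pcr_duplicate_rate / (1.0 - cfg.pcr_duplicate_rate)
                      if cfg.pcr_duplicate_rate > 0 else 0.0)
        n_prot = cfg.n_protected_per_original
        mol_id = 0
        variants_by_contig: dict[str, list[PlantedVariant]] = {}
        for v in cfg.planted_variants:
            variants_by_contig.setdefault(v.contig, []).append(v)
        asm_by_contig: dict[str, list[ASMEffect]] = {}
        for eff in cfg.asm_effects:
            asm_by_contig.setdefault(eff.contig, []).append(eff)

        for contig, spec in cfg.contigs.items():
            arr = arrays[contig]
            pos_all = cpg_pos[contig]
            beta_all = cpg_beta[contig]
            l_max = min(cfg.fragment_length, spec.length)
            l_min = min(cfg.fragment_length_min, l_max)
            for _ in range(spec.n_molecules):
                mol_id += 1
                L = int(rng.integers(l_min, l_max + 1))
                start = int(rng.integers(0, spec.length - L + 1))
                end = start + L
                mol = arr[start:end].copy()
                carried: list[tuple[int, str]] = []
                for v in variants_by_contig.get(contig, []):
                    if start <= v.position < end and rng.random() < v.allele_fraction:
                        mol[v.position - start] = ord(v.alt)
                        carried.append((v.position, v.alt))
                lo = np.searchsorted(pos_all, start)
                hi = np.searchsorted(pos_all, end - 1)  # dyad needs p+1 < end
                dpos = pos_all[lo:hi]
                if spec.kind == "puc19":
                    state = np.full(dpos.size,
                                    rng.random() < spec.methylation_level, dtype=bool)
                elif spec.kind == "lambda":
                    state = np.zeros(dpos.size, dtype=bool)
                else:
                    state = rng.random(dpos.size) < beta_all[lo:hi]
                    for eff in asm_by_contig.get(contig, []):
                        if start <= eff.snp_position < end:
                            is_alt = any(p == eff.snp_position for p, _ in carried)
                            b = eff.beta_alt if is_alt else eff.beta_ref
                            near = np.abs(dpos - eff.snp_position) <= eff.window
                            state[near] = rng.random(int(near.sum())) < b
                truth.molecule_cpgs[mol_id] = {int(p): int(s)
                                               for p, s in zip(dpos, state)}
                umi_a = self.pool.umis[int(rng.integers(len(self.pool)))]
                umi_b = self.pool.umis[int(rng.integers(len(self.pool)))]

                strands = [(Stream.METH, WATSON), (Stream.METH, CRICK)]
                strands += [(Stream.GENET, WATSON)] * n_prot
                strands += [(Stream.GENET, CRICK)] * n_prot
                for s_i, (stream, sense) in enumerate(strands):
                    truth.n_strands_total += 1
                    if rng.random() > cfg.strand_survival:
                        continue
                    truth.n_strands_surviving += 1
                    obs, obs_states = self._observe_strand(
                        mol, start, dpos, state, stream, sense)
                    u1_src, u2_src = (umi_a, umi_b) if sense == WATSON else (umi_b, umi_a)
                    conv_p = (cfg.conversion_sensitivity if stream is Stream.METH
                              else 1.0 - cfg.analog_resistance)
                    u1_obs = _convert_umi(rng, u1_src, "C", conv_p)
                    u2_obs = _convert_umi(rng, u2_src, "G", conv_p)
                    flags = _FLAGS[(stream, sense)]
                    plus_seq = obs.tobytes().decode()
                    n_copies = 1 + (int(rng.poisson(dup_lambda)) if dup_lambda else 0)
                    truth.n_duplicates += n_copies - 1
                    for k in range(n_copies):
                        name = f"m{mol_id}:{sense[0]}:{stream.value[0]}{s_i}:{k}"
                        truth.records[name] = TruthRecord(
                            name=name, molecule_id=mol_id, contig=contig,
                            start=start, end=end, strand=sense, stream=stream,
                            umi1=u1_src, umi2=u2_src, is_duplicate=k > 0,
                            variants=tuple(carried))
                        fragments.append(AlignedFragment(
                            contig=contig, start=start, end=end,
                            flag1=flags[0], flag2=flags[1],
                            umi1=u1_obs, umi2=u2_obs, stream=stream,
                            bases=plus_seq,
                            cpg_states=dict(obs_states) if stream is Stream.METH else {},
                            name=name))
                        if cfg.emit_reads:
                            r1_gen = plus_seq if sense == WATSON else revcomp(plus_seq)
                            r1 = u1_obs + r1_gen
                            r2 = u2_obs + revcomp(r1_gen)
                            q = "I" * len(r1)
                            read_pairs.append(ReadPair(name, r1, r2, q, "I" * len(r2)))

        reference = {name: arr.tobytes().decode() for name, arr in arrays.items()}
        return SimResult(reference=reference, pool=self.pool,
                         read_pairs=read_pairs, fragments=fragments, truth=truth)


def simulate_library(config: SimConfig, pool: UMIPool | None = None) -> SimResult:
    """Generate a truth-labelled MM-seq library from ``config``."""
    return LibrarySimulator(config, pool=pool).run()
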
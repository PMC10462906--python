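"""Synthetic multi-GC lymph-node repertoire generator with ground truth.

The generator emulates the structure of a laser-capture-microdissected
human lymph node experiment: ``n_gcs`` germinal centers, each sequenced in
two replicate amplifications, populated by clones whose sizes follow a
stick-breaking (GEM) law so that per-GC clonal dominance spans roughly
5–30%. Clones occupy their home GC plus ``Poisson(mu)`` additional GCs
(recirculation); in a non-home GC a clone enters at a disadvantage and its
abundance is down-scaled. Somatic hypermutation places substitutions with
a CDR-elevated rate; non-functional sequences arise as frameshifts
(out-of-frame junction), V(D)J-derived stop codons planted inside the N1
region, or SHM-derived "crippling" stops appearing after an average of
``mean_mutations_before_crippling`` neutral mutations. A configurable
fraction of out-of-frame clones is emitted as the silenced second allele
of a functional clone at matched abundance. Convergent-evolution test
beds are planted as groups of distinct clones (same V/J and CDR3 length,
junction identity well below the clonal threshold) that share a paratope
template.

Everything is deterministic under ``seed``.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .germlines import (
    GERMLINE_J,
    GERMLINE_V,
    J_LENGTH,
    V_LENGTH,
    V_REGION_BOUNDS,
    v_gene_of,
)
from .io import RearrangementRecord

__all__ = ["LymphNodeConfig", "GroundTruth", "generate_lymph_node", "generate_paratopes"]

_STOPS = {"TAA", "TAG", "TGA"}
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# the conserved J-TRP codon of FWR2 (TGG at nt 105..108 of every V gene);
# a single G->A substitution turns it into TAG, the planted crippling site
_CRIPPLE_CODON_START = V_REGION_BOUNDS["fwr2"][0] + 6


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class LymphNodeConfig:
    """Stated world of the synthetic lymph node.

    Defaults reproduce the observed conditions: 10 GCs x 2 replicates,
    ~90% functional sequences with non-functional mass split 78/11/11
    between frameshifts, V(D)J stops and SHM stops, recirculation rate
    mu = 0.25, and 3.6 mutations on average before a crippling stop.
    ``seqs_per_sample`` defaults to 5,000 (desk scale; the experiment is
    ~100,000 per sample).
    """

    n_gcs: int = 10
    n_replicates: int = 2
    seqs_per_sample: int = 5000
    n_clones_per_gc: int = 400
    sharing_rate_mu: float = 0.25
    functional_fraction: float = 0.90
    nf_composition: tuple[float, float, float] = (0.78, 0.11, 0.11)  # oof, vdj, shm
    dominance_concentration: float = 12.0
    shm_mean_mutations: float = 5.0
    shm_rate_cdr_multiplier: float = 3.0
    mean_mutations_before_crippling: float = 3.6
    post_crippling_mutations: float = 1.0
    crippled_nf_fraction: float = 0.3
    allele_pair_fraction: float = 0.3
    visitor_downscale: float = 0.1
    replicate_dropout: float = 0.0
    n_epitopes: int = 5
    epitope_group_size: int = 4
    paratope_noise: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if self.n_gcs < 1 or self.n_replicates < 1 or self.seqs_per_sample < 1:
            raise ConfigError("n_gcs, n_replicates and seqs_per_sample must be >= 1")
        if self.n_clones_per_gc < 1:
            raise ConfigError("n_clones_per_gc must be >= 1")
        for name in ("functional_fraction", "allele_pair_fraction",
                     "visitor_downscale", "replicate_dropout", "crippled_nf_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if abs(sum(self.nf_composition) - 1.0) > 1e-9:
            raise ConfigError("nf_composition must sum to 1")
        if self.sharing_rate_mu < 0:
            raise ConfigError("sharing_rate_mu must be >= 0")
        if self.dominance_concentration <= 0:
            raise ConfigError("dominance_concentration must be > 0")


@dataclass
class GroundTruth:
    """Latent state of the generator, one row per emitted record / clone."""

    sequences: pd.DataFrame  # sequence_id, clone, func_class, gc_id, replicate_id
    clones: pd.DataFrame     # clone, home_gc, occupancy, clone_type, epitope_group,
                             # partner, n_premutations, v_call, j_call
    v_usage_skew: tuple[str, ...] = ()

    @property
    def clone_assignments(self) -> dict[str, int]:
        return dict(zip(self.sequences["sequence_id"], self.sequences["clone"]))


@dataclass
class _Founder:
    """Internal per-clone latent state."""

    idx: int
    v_call: str
    j_call: str
    cdr3: str                       # in-frame, stop-free (before any crippling edit)
    home_gc: int
    gcs: tuple[int, ...]            # occupied GCs (home first)
    n1_len: int
    n2_len: int
    clone_type: str                 # functional | out_of_frame | vdj_stop
    crippled: bool = False
    n_premutations: int = 0
    epitope_group: int = -1
    partner: int = -1               # functional clone this NF allele pairs with
    weight: dict[int, float] = field(default_factory=dict)  # per-GC raw weight


def _random_cdr3(rng: np.random.Generator, n_codons: int) -> str:
    codons = []
    for _ in range(n_codons):
        c = "".join("ACGT"[i] for i in rng.integers(0, 4, size=3))
        while c in _STOPS:
            c = "".join("ACGT"[i] for i in rng.integers(0, 4, size=3))
        codons.append(c)
    return "".join(codons)


def _has_stop(arr: np.ndarray) -> bool:
    """Any stop codon in frame 0 of a byte array (length need not be %3)."""
    n = (arr.size // 3) * 3
    c = arr[:n].reshape(-1, 3)
    t = c[:, 0] == ord("T")
    a = c[:, 1] == ord("A")
    g2 = c[:, 2] == ord("G")
    a2 = c[:, 2] == ord("A")
    return bool(
        np.any(t & a & (a2 | g2)) or np.any(t & (c[:, 1] == ord("G")) & a2)
    )


def _stop_overlapping(arr: np.ndarray, intervals: list[tuple[int, int]]) -> bool:
    """Any in-frame stop codon whose span overlaps one of the intervals."""
    n = (arr.size // 3) * 3
    for i in range(0, n, 3):
        codon = arr[i : i + 3].tobytes().decode("ascii")
        if codon in _STOPS:
            for s, e in intervals:
                if i < e and i + 3 > s:
                    return True
    return False


class _CloneVariant:
    """A concrete emissible sequence lineage of a founder clone."""

    __slots__ = ("base", "mut_weights", "func_class", "bounds", "n_bounds",
                 "junction_span", "in_frame", "protected")

    def __init__(self, base, mut_weights, func_class, bounds, n_bounds,
                 junction_span, in_frame):
        self.base = base
        self.mut_weights = mut_weights
        self.func_class = func_class
        self.bounds = bounds
        self.n_bounds = n_bounds
        self.junction_span = junction_span
        self.in_frame = in_frame


def _region_bounds(cdr3_len: int) -> dict[str, tuple[int, int]]:
    b = dict(V_REGION_BOUNDS)
    b["cdr3"] = (V_LENGTH, V_LENGTH + cdr3_len)
    b["fwr4"] = (V_LENGTH + cdr3_len, V_LENGTH + cdr3_len + J_LENGTH)
    return b


def _cdr_weight_mask(length: int, bounds: dict, multiplier: float) -> np.ndarray:
    w = np.ones(length)
    for r in ("cdr1", "cdr2", "cdr3"):
        s, e = bounds[r]
        w[s:e] = multiplier
    return w


def _build_variants(f: _Founder, cfg: LymphNodeConfig,
                    rng: np.random.Generator) -> dict[str, _CloneVariant]:
    """Assemble the emissible lineages (functional / NF) of one founder."""
    v_nt = GERMLINE_V[v_gene_of(f.v_call)]
    j_nt = GERMLINE_J[v_gene_of(f.j_call)]
    cdr3 = f.cdr3
    L = len(cdr3)
    seq = v_nt + cdr3 + j_nt
    bounds = _region_bounds(L)
    jspan = (V_LENGTH - 3, V_LENGTH + L + 3)
    n_bounds = [(V_LENGTH, V_LENGTH + f.n1_len),
                (V_LENGTH + L - f.n2_len, V_LENGTH + L)]
    variants: dict[str, _CloneVariant] = {}

    def arr_of(s: str) -> np.ndarray:
        return np.frombuffer(s.encode("ascii"), dtype=np.uint8).copy()

    if f.clone_type == "out_of_frame":
        # frameshift: drop one nt from the D segment (between N1 and N2)
        pos = V_LENGTH + f.n1_len  # first D position, inside the junction
        arr = np.delete(arr_of(seq), pos)
        b = dict(bounds)
        b["cdr3"] = (V_LENGTH, V_LENGTH + L - 1)
        b["fwr4"] = (V_LENGTH + L - 1, V_LENGTH + L - 1 + J_LENGTH)
        nb = [(V_LENGTH, V_LENGTH + f.n1_len),
              (V_LENGTH + L - 1 - f.n2_len, V_LENGTH + L - 1)]
        w = _cdr_weight_mask(arr.size, b, cfg.shm_rate_cdr_multiplier)
        variants["out_of_frame"] = _CloneVariant(
            arr, w / w.sum(), "out_of_frame", b, nb,
            (V_LENGTH - 3, V_LENGTH + L - 1 + 3), False)
        return variants

    if f.clone_type == "vdj_stop":
        # recombination-derived stop: first N1 codon becomes TAG
        arr = arr_of(seq)
        arr[V_LENGTH : V_LENGTH + 3] = np.frombuffer(b"TAG", dtype=np.uint8)
        w = _cdr_weight_mask(arr.size, bounds, cfg.shm_rate_cdr_multiplier)
        w[V_LENGTH : V_LENGTH + 3] = 0.0  # the planted stop is never touched
        variants["vdj_stop"] = _CloneVariant(
            arr, w / w.sum(), "vdj_stop", bounds, n_bounds, jspan, True)
        return variants

    # functional lineage
    arr = arr_of(seq)
    w = _cdr_weight_mask(arr.size, bounds, cfg.shm_rate_cdr_multiplier)
    if f.epitope_group >= 0:
        # antigen selection conserves the paratope loops of convergent
        # clones: CDR1/CDR2 are frozen (their germline V already encodes
        # the shared binding mode)
        for r in ("cdr1", "cdr2"):
            s, e = bounds[r]
            w[s:e] = 0.0
    variants["functional"] = _CloneVariant(
        arr, w / w.sum(), "functional", bounds, n_bounds, jspan, True)

    if f.crippled:
        # shared pre-crippling mutations, then an SHM stop in FWR2
        carr = arr.copy()
        wpre = w.copy()
        wpre[_CRIPPLE_CODON_START : _CRIPPLE_CODON_START + 3] = 0.0
        p = wpre / wpre.sum()
        for _ in range(200):  # place n_premutations without creating a stop
            trial = arr.copy()
            pos = rng.choice(carr.size, size=f.n_premutations, replace=False, p=p)
            for q in pos:
                choices = _BASES[_BASES != trial[q]]
                trial[q] = rng.choice(choices)
            if not _has_stop(trial):
                carr = trial
                break
        carr[_CRIPPLE_CODON_START + 1] = ord("A")  # TGG -> TAG
        wnf = w.copy()
        wnf[_CRIPPLE_CODON_START : _CRIPPLE_CODON_START + 3] = 0.0
        variants["shm_stop"] = _CloneVariant(
            carr, wnf / wnf.sum(), "shm_stop", bounds, n_bounds, jspan, True)
    return variants


def _mutate_cell(variant: _CloneVariant, n_mut: int,
                 rng: np.random.Generator) -> np.ndarray:
    """One cell's sequence: the lineage base plus ``n_mut`` substitutions.

    Functional cells never acquire a stop codon (GC selection removes such
    cells); shm_stop cells never acquire a stop overlapping an N region
    (which would mimic a recombination error).
    """
    if n_mut == 0:
        return variant.base
    arr = variant.base
    for _ in range(12):
        trial = arr.copy()
        pos = rng.choice(arr.size, size=n_mut, replace=False, p=variant.mut_weights)
        for q in pos:
            choices = _BASES[_BASES != trial[q]]
            trial[q] = rng.choice(choices)
        if variant.func_class == "functional":
            if not _has_stop(trial):
                return trial
        elif variant.func_class == "shm_stop":
            if not _stop_overlapping(trial, variant.n_bounds):
                return trial
        else:
            return trial
    return arr  # fall back to the unmutated lineage base


def generate_lymph_node(
    config: LymphNodeConfig,
) -> tuple[list[RearrangementRecord], GroundTruth]:
    """Generate the full synthetic lymph node and its latent truth."""
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    v_names = list(GERMLINE_V)
    j_names = list(GERMLINE_J)

    # skewed V usage: three planted high-usage genes carry 60% of the mass
    skew = tuple(v_names[i] for i in rng.choice(len(v_names), 3, replace=False))
    v_weights = np.full(len(v_names), 0.4 / (len(v_names) - 3))
    for g in skew:
        v_weights[v_names.index(g)] = 0.2

    p_oof = (1 - cfg.functional_fraction) * cfg.nf_composition[0]
    p_vdj = (1 - cfg.functional_fraction) * cfg.nf_composition[1]
    p_shm = (1 - cfg.functional_fraction) * cfg.nf_composition[2]
    p_func = 1.0 - p_oof - p_vdj
    # fraction of functional clones carrying a crippled sublineage such
    # that the expected shm_stop sequence mass matches nf_composition
    f_cripple = 0.0
    if p_shm > 0 and cfg.crippled_nf_fraction > 0:
        f_cripple = min(1.0, p_shm / (p_func * cfg.crippled_nf_fraction))

    founders: list[_Founder] = []

    def new_founder(home_gc: int, clone_type: str, v_call=None, j_call=None,
                    cdr3=None) -> _Founder:
        idx = len(founders)
        if v_call is None:
            v_call = v_names[rng.choice(len(v_names), p=v_weights)] + "*01"
        if j_call is None:
            j_call = j_names[rng.integers(0, len(j_names))] + "*01"
        if cdr3 is None:
            cdr3 = _random_cdr3(rng, int(rng.integers(10, 18)))
        L = len(cdr3)
        n1 = int(rng.integers(3, min(9, L - 6)))
        n2 = int(rng.integers(2, 6))
        extra = int(rng.poisson(cfg.sharing_rate_mu))
        others = [g for g in range(cfg.n_gcs) if g != home_gc]
        extra = min(extra, len(others))
        visited = (home_gc, *(int(g) for g in rng.choice(others, extra, replace=False))) \
            if extra else (home_gc,)
        f = _Founder(idx, v_call, j_call, cdr3, home_gc, visited, n1, n2, clone_type)
        founders.append(f)
        return f

    for gc in range(cfg.n_gcs):
        for _ in range(cfg.n_clones_per_gc):
            new_founder(gc, "functional")  # type quota-assigned below

    # planted convergent-epitope groups: same V/J and CDR3 length,
    # scattered across GCs; the per-member substitution rate (10% nt of the
    # prototype CDR3) puts pairwise CDR3 amino-acid similarity in the
    # 0.6-0.75 band characteristic of convergent pairs while keeping
    # junction identity below the clonal threshold
    for g in range(cfg.n_epitopes):
        proto_v = v_names[rng.choice(len(v_names), p=v_weights)] + "*01"
        proto_j = j_names[rng.integers(0, len(j_names))] + "*01"
        proto = _random_cdr3(rng, int(rng.integers(12, 16)))
        n_codons = len(proto) // 3
        for m in range(cfg.epitope_group_size):
            codons = [proto[i : i + 3] for i in range(0, len(proto), 3)]
            # substitutions cluster within codons (2 nt each): pairwise
            # CDR3 amino-acid similarity lands in the 0.6-0.75 band of
            # convergent pairs while junction nucleotide identity stays
            # well below the clonal threshold
            k = max(2, int(round(0.2 * n_codons)))
            for q in rng.choice(n_codons, k, replace=False):
                old = codons[q]
                while True:
                    cand = "".join("ACGT"[i] for i in rng.integers(0, 4, size=3))
                    diff = sum(x != y for x, y in zip(cand, old))
                    if cand not in _STOPS and diff >= 2:
                        break
                codons[q] = cand
            f = new_founder((g * cfg.epitope_group_size + m) % cfg.n_gcs,
                            "functional", proto_v, proto_j, "".join(codons))
            f.epitope_group = g

    # GEM clone sizes per GC; planted epitope clones get a fixed 0.5-2%
    # foothold so they are recoverable among the dominant clones
    for gc in range(cfg.n_gcs):
        home = [f for f in founders if f.home_gc == gc]
        alpha = cfg.dominance_concentration
        remaining = 1.0
        sticks = []
        for _ in range(len(home) - 1):
            b = rng.beta(1.0, alpha)
            sticks.append(remaining * b)
            remaining *= 1.0 - b
        sticks.append(remaining)
        order = rng.permutation(len(home))
        for f, s in zip(home, np.asarray(sticks)[order]):
            f.weight[gc] = float(s)
        for f in home:
            if f.epitope_group >= 0:
                f.weight[gc] = float(rng.uniform(0.005, 0.02))
        total = sum(f.weight[gc] for f in home)
        for f in home:  # keep home weights normalised so the functionality
            f.weight[gc] /= total  # quotas below are in realised-share units

    # clone functionality: membership is drawn independently of clone size
    # (except that a clone without a surface BCR cannot be positively
    # selected, so clones above 5% of their GC stay functional and are not
    # crippled), then each type group's weights are rescaled so the
    # emitted sequence mass matches functional_fraction / nf_composition
    # exactly — the stated composition is a property of the repertoire,
    # not of clone counts
    q = cfg.crippled_nf_fraction
    m_crip_target = p_shm / q if (q > 0 and p_shm > 0) else 0.0
    m_func_target = p_func - m_crip_target
    for gc in range(cfg.n_gcs):
        home = [f for f in founders if f.home_gc == gc]
        for f in home:
            if f.epitope_group >= 0 or f.weight[gc] > 0.05:
                continue
            u = rng.random()
            if u < p_oof:
                f.clone_type = "out_of_frame"
            elif u < p_oof + p_vdj:
                f.clone_type = "vdj_stop"
            elif f_cripple > 0 and rng.random() < f_cripple:
                f.crippled = True
                f.n_premutations = int(
                    rng.poisson(cfg.mean_mutations_before_crippling))
        groups = {
            "functional": (m_func_target,
                           [f for f in home if f.clone_type == "functional"
                            and not f.crippled]),
            "crippled": (m_crip_target,
                         [f for f in home if f.crippled]),
            "out_of_frame": (p_oof,
                             [f for f in home if f.clone_type == "out_of_frame"]),
            "vdj_stop": (p_vdj,
                         [f for f in home if f.clone_type == "vdj_stop"]),
        }
        achievable = sum(t for t, fs in groups.values() if fs)
        for target, fs in groups.values():
            if not fs:
                continue
            mass = sum(f.weight[gc] for f in fs)
            scale = (target / achievable) / mass
            for f in fs:
                f.weight[gc] *= scale

    # silenced-allele pairing: part of the out-of-frame mass budget is
    # spent on second alleles that track a functional clone's abundance
    # (both alleles share the clone's cell count; only the alleles of
    # reasonably expanded clones rise above the detection floor, so
    # partners are drawn from a mid-dominance band)
    for gc in range(cfg.n_gcs):
        oof = sorted((f for f in founders
                      if f.home_gc == gc and f.clone_type == "out_of_frame"),
                     key=lambda f: (-f.weight[gc], f.idx))
        band = [f for f in founders
                if f.home_gc == gc and f.clone_type == "functional"
                and f.epitope_group < 0 and not f.crippled
                and 0.004 <= f.weight[gc] <= 0.03]
        partner_budget = cfg.allele_pair_fraction * p_oof
        spent = 0.0
        order = rng.permutation(len(band))
        paired: list[tuple[_Founder, _Founder]] = []
        for f_oof, bi in zip(oof, order):
            partner = band[bi]
            w = partner.weight[gc] * float(2.0 ** rng.normal(0, 0.25))
            if spent + w > partner_budget:
                break
            f_oof.partner = partner.idx
            f_oof.weight[gc] = w
            spent += w
            paired.append((f_oof, partner))
        # keep the total out-of-frame mass on budget: the unpaired
        # out-of-frame clones are rescaled into the remaining budget
        free = [f for f in founders
                if f.home_gc == gc and f.clone_type == "out_of_frame"
                and f.partner < 0]
        free_mass = sum(f.weight[gc] for f in free)
        if free and free_mass > 0:
            scale = max(p_oof - spent, 0.0) / free_mass
            for f in free:
                f.weight[gc] *= scale

    # visitor weights
    for f in founders:
        for gc in f.gcs[1:]:
            f.weight[gc] = f.weight[f.home_gc] * cfg.visitor_downscale

    # per-founder variant cache
    variant_cache = [_build_variants(f, cfg, rng) for f in founders]

    records: list[RearrangementRecord] = []
    truth_rows: list[tuple] = []
    for gc in range(cfg.n_gcs):
        present = [f for f in founders if gc in f.gcs]
        w = np.array([f.weight[gc] for f in present])
        p = w / w.sum()
        for rep in range(cfg.n_replicates):
            counts = rng.multinomial(cfg.seqs_per_sample, p)
            if cfg.replicate_dropout > 0:
                drop = rng.random(counts.size) < cfg.replicate_dropout
                counts = np.where(drop, 0, counts)
            gc_id, rep_id = f"GC{gc + 1}", f"R{rep + 1}"
            for f, c in zip(present, counts):
                if c == 0:
                    continue
                variants = variant_cache[f.idx]
                plan: list[tuple[_CloneVariant, int]] = []
                if f.crippled:
                    n_nf = int(rng.binomial(c, cfg.crippled_nf_fraction))
                    if n_nf:
                        plan.append((variants["shm_stop"], n_nf))
                    if c - n_nf:
                        plan.append((variants["functional"], c - n_nf))
                else:
                    plan.append((next(iter(variants.values())), int(c)))
                for variant, n_cells in plan:
                    seen: dict[bytes, int] = {}
                    # a crippled cell loses its BCR and apoptoses within a
                    # couple of divisions, so it accumulates little further SHM
                    mean_mut = (cfg.post_crippling_mutations
                                if variant.func_class == "shm_stop"
                                else cfg.shm_mean_mutations)
                    n_muts = rng.poisson(mean_mut, size=n_cells)
                    for m in n_muts:
                        cell = _mutate_cell(variant, int(m), rng)
                        key = cell.tobytes()
                        seen[key] = seen.get(key, 0) + 1
                    for serial, (key, dup) in enumerate(seen.items()):
                        seq = key.decode("ascii")
                        js, je = variant.junction_span
                        sid = f"{gc_id}_{rep_id}_c{f.idx}_{variant.func_class[:3]}{serial}"
                        records.append(RearrangementRecord(
                            sequence_id=sid,
                            gc_id=gc_id,
                            replicate_id=rep_id,
                            sequence=seq,
                            v_call=f.v_call,
                            j_call=f.j_call,
                            junction=seq[js:je],
                            junction_length=je - js,
                            region_bounds=dict(variant.bounds),
                            n_region_bounds=list(variant.n_bounds),
                            in_frame_junction=variant.in_frame,
                            duplicate_count=int(dup),
                        ))
                        truth_rows.append(
                            (sid, f.idx, variant.func_class, gc_id, rep_id))

    seq_df = pd.DataFrame(
        truth_rows,
        columns=["sequence_id", "clone", "func_class", "gc_id", "replicate_id"])
    clone_df = pd.DataFrame(
        {
            "clone": [f.idx for f in founders],
            "home_gc": [f"GC{f.home_gc + 1}" for f in founders],
            "occupancy": [len(f.gcs) for f in founders],
            "clone_type": [
                ("crippled" if f.crippled else f.clone_type) for f in founders],
            "epitope_group": [f.epitope_group for f in founders],
            "partner": [f.partner for f in founders],
            "n_premutations": [f.n_premutations for f in founders],
            "v_call": [f.v_call for f in founders],
            "j_call": [f.j_call for f in founders],
        }
    )
    return records, GroundTruth(seq_df, clone_df, skew)


# --------------------------------------------------------------------------
# paratope / coordinate emission for convergence analyses
# --------------------------------------------------------------------------

def _aa_positions(bounds: dict[str, tuple[int, int]]) -> dict[str, range]:
    return {r: range(s // 3, e // 3) for r, (s, e) in bounds.items()}


def _numbering(bounds: dict[str, tuple[int, int]], n_aa: int) -> list[int]:
    """Stable per-residue numbering: V residues keep their index, CDR3
    residues are offset to 200+, J residues to 400+, so that residues only
    align across clones when they play the same structural role."""
    cdr3 = _aa_positions(bounds)["cdr3"]
    out = []
    for i in range(n_aa):
        if i < cdr3.start:
            out.append(i)
        elif i in cdr3:
            out.append(200 + (i - cdr3.start))
        else:
            out.append(400 + (i - cdr3.stop))
    return out


def generate_paratopes(clones, truth: GroundTruth, config: LymphNodeConfig):
    """Emit per-clone paratope probabilities, masks and toy coordinates.

    Clones mapped (via the truth channel) to the same planted epitope group
    receive perturbed copies of a shared template — similar masks and
    coordinates; all other clones receive independent templates. Returns a
    list of :class:`~gcrepertoire.convergence.ParatopeProfile`.
    """
    from .convergence import PARATOPE_PROB_THRESHOLD, ParatopeProfile
    from Bio.Seq import Seq

    assign = truth.clone_assignments
    group_of = dict(zip(truth.clones["clone"], truth.clones["epitope_group"]))
    templates: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}
    profiles = []
    for clone in clones:
        rep = clone.representative
        if rep is None or not rep.in_frame_junction:
            continue
        if "cdr1" not in rep.region_bounds or "cdr3" not in rep.region_bounds:
            continue
        aa = str(Seq(rep.sequence).translate())
        pos = _aa_positions(rep.region_bounds)
        n_aa = len(aa)
        founder = assign.get(rep.sequence_id, -1)
        group = group_of.get(founder, -1)
        if group >= 0:
            tkey = (group, n_aa)
            rng = np.random.default_rng(
                (config.seed, 7001, group, n_aa, zlib.crc32(rep.sequence_id.encode())))
        else:
            tkey = None
            rng = np.random.default_rng(
                (config.seed, 7002, zlib.crc32(rep.sequence_id.encode())))
        if tkey is not None and tkey not in templates:
            trng = np.random.default_rng((config.seed, 7000, group, n_aa))
            templates[tkey] = _make_template(trng, pos, n_aa)
        if tkey is not None:
            base_probs, base_coords = templates[tkey]
        else:
            base_probs, base_coords = _make_template(rng, pos, n_aa)
        probs = np.clip(base_probs + rng.normal(0, config.paratope_noise, n_aa), 0, 1)
        coords = base_coords + rng.normal(0, config.paratope_noise, (n_aa, 3))
        mask = probs >= PARATOPE_PROB_THRESHOLD
        profiles.append(ParatopeProfile(
            clone_id=clone.clone_id,
            aa_sequence=aa,
            cdr_seqs=(
                aa[pos["cdr1"].start:pos["cdr1"].stop],
                aa[pos["cdr2"].start:pos["cdr2"].stop],
                aa[pos["cdr3"].start:pos["cdr3"].stop],
            ),
            residue_probs=probs,
            paratope_mask=mask,
            coords=coords,
            numbering=_numbering(rep.region_bounds, n_aa),
        ))
    return profiles


def _make_template(rng: np.random.Generator, pos: dict[str, range],
                   n_aa: int) -> tuple[np.ndarray, np.ndarray]:
    """A paratope template: CDR1+CDR2 plus ~60% of CDR3 are paratope."""
    probs = np.full(n_aa, 0.1)
    for r in ("cdr1", "cdr2"):
        probs[pos[r].start:pos[r].stop] = 0.9
    cdr3 = list(pos["cdr3"])
    k = max(3, int(round(0.6 * len(cdr3))))
    chosen = rng.choice(cdr3, size=k, replace=False)
    probs[chosen] = 0.9
    idx = np.arange(n_aa)
    coords = np.stack([
        1.5 * idx,
        4.0 * np.sin(0.7 * idx),
        4.0 * np.cos(0.7 * idx),
    ], axis=1) + rng.normal(0, 2.0, (n_aa, 3))
    return probs, coords
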
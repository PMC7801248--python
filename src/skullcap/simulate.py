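"""Synthetic genome-pair evolution with planted, logged events.

The generator produces two present-day genomes descending from a common
ancestor through an optional whole-genome duplication (WGD), a speciation
split, lineage-specific tandem duplications and inversions — together with a
truth table of every pair's true synonymous divergence, so each downstream
stage (synteny, Ka/Ks, dating, LTR ages, compartments) can be scored against
ground truth.

Sequence divergence model
-------------------------
Substitutions are planted per site under a Jukes-Cantor clock: a branch of
t years at synonymous rate mu gives per-site difference probability
p = 3/4 (1 - exp(-8 mu t / 3)), i.e. the JC expectation for K = 2 mu t.
Nonsynonymous changes accrue at omega times the synonymous rate. Each of the
three possible single-base changes at a codon position occurs with
probability p_class/(3 - #to-stop-changes), with the class (synonymous /
nonsynonymous) taken per change from the current codon; changes to stop
codons never occur. Under this kernel the expected NG86 proportions satisfy
E[Sd/S] = p_syn and E[Nd/N] = p_nonsyn for any codon composition, so the
estimator under test is consistent with the planted truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil, exp

import numpy as np

from ._codons import SENSE_INDEX, decode_codons, encode_codons, mutation_tables
from .io import GeneModel, Genome

__all__ = [
    "ConfigurationError",
    "EvolutionScenario",
    "LTRElementSim",
    "PlaidConfig",
    "TandemEvent",
    "InversionEvent",
    "TruthTable",
    "mutate_sequence",
    "simulate_cds_pairs",
    "simulate_genome_pair",
    "simulate_ltr_set",
    "simulate_contact_matrix",
]


class ConfigurationError(ValueError):
    """An impossible scenario (e.g. inconsistent event ordering)."""


def jc_p(mu: float, t: float) -> float:
    """Expected per-site difference fraction after 2*mu*t substitutions/site."""
    return 0.75 * (1.0 - exp(-8.0 * mu * t / 3.0))


# ---------------------------------------------------------------- scenario


@dataclass
class TandemEvent:
    lineage: str          # 'A' or 'B'
    age: float            # years before present
    source_index: int     # index into the lineage's gene list at the event
    copies: int = 1       # new copies in addition to the template
    spacing_bp: int = 2000


@dataclass
class InversionEvent:
    lineage: str
    chromosome: str
    span: tuple[int, int]  # gene-index span [lo, hi) on the chromosome


@dataclass
class EvolutionScenario:
    """Planted evolutionary history for one genome pair.

    Ages are years before present; rates are per site per year. A shared WGD
    must precede the speciation split (wgd_age > speciation_age); a
    lineage-specific WGD (wgd_lineage 'A' or 'B') must postdate it.
    """

    n_chromosomes: int = 2
    genes_per_chromosome: int = 60
    cds_length_codons: tuple[int, int] = (150, 300)
    wgd_age: float | None = 33.46e6
    wgd_lineage: str = "shared"
    speciation_age: float = 6.15e6
    syn_rate_mu: float = 1.3e-8
    omega: float = 0.13
    tandem_events: list[TandemEvent] = field(default_factory=list)
    inversion_events: list[InversionEvent] = field(default_factory=list)
    gene_loss_fraction_post_wgd: float = 0.4
    intergenic_bp: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.speciation_age < 0 or (self.wgd_age is not None and self.wgd_age < 0):
            raise ConfigurationError("event ages must be >= 0")
        if self.syn_rate_mu <= 0:
            raise ConfigurationError("syn_rate_mu must be > 0")
        if not 0.0 <= self.omega <= 1.0:
            raise ConfigurationError("omega must be in [0, 1]")
        if not 0.0 <= self.gene_loss_fraction_post_wgd < 1.0:
            raise ConfigurationError("gene_loss_fraction_post_wgd must be in [0, 1)")
        if self.wgd_lineage not in ("shared", "A", "B"):
            raise ConfigurationError("wgd_lineage must be 'shared', 'A' or 'B'")
        if self.wgd_age is not None:
            if self.wgd_lineage == "shared" and self.wgd_age <= self.speciation_age:
                raise ConfigurationError(
                    f"shared WGD (age {self.wgd_age}) must precede speciation "
                    f"(age {self.speciation_age})")
            if self.wgd_lineage != "shared" and self.wgd_age >= self.speciation_age:
                raise ConfigurationError(
                    f"lineage-{self.wgd_lineage} WGD (age {self.wgd_age}) must "
                    f"postdate speciation (age {self.speciation_age})")
        for ev in self.tandem_events:
            if ev.lineage not in ("A", "B"):
                raise ConfigurationError(f"tandem event lineage {ev.lineage!r}")
            if not 0 <= ev.age < self.speciation_age and self.speciation_age > 0:
                raise ConfigurationError(
                    f"tandem event (age {ev.age}) must postdate speciation "
                    f"(age {self.speciation_age})")


@dataclass
class TruthTable:
    """Ground truth: pair divergences (in K = 2*mu*age units) and event log."""

    ortholog_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    paralog_pairs: list[tuple[str, str, str, str, float, float]] = field(
        default_factory=list)  # genome, a, b, event, age, divergence
    rearrangements: list[str] = field(default_factory=list)
    gene_history: dict[str, str] = field(default_factory=dict)

    def paralogs_of(self, genome: str, event: str | None = None):
        return [p for p in self.paralog_pairs
                if p[0] == genome and (event is None or p[3] == event)]


@dataclass
class LTRElementSim:
    element_id: str
    chromosome: str
    start: int
    end: int
    ltr5_seq: str
    ltr3_seq: str
    true_age: float


# ---------------------------------------------------------------- mutation


def mutate_sequence(cds: str, syn_p: float, nonsyn_p: float,
                    seed_or_rng) -> str:
    """Plant substitutions on a CDS at given per-site class probabilities.

    Each possible single-base change occurs with probability
    p_class/(3 - #to-stop changes) at its position; substitutions creating
    stop codons are rejected. Probabilities must lie in [0, 0.75) (the JC
    inverse is undefined at saturation). Length is preserved.
    """
    for p in (syn_p, nonsyn_p):
        if not 0.0 <= p < 0.75:
            raise ValueError(f"class probability {p} outside [0, 0.75)")
    rng = np.random.default_rng(seed_or_rng) if isinstance(seed_or_rng, (int, np.integer)) \
        else seed_or_rng
    idx = encode_codons(cds)
    alt_codon, cls, tau, is_stop = mutation_tables()
    if is_stop[idx].any():
        where = int(np.nonzero(is_stop[idx])[0][0])
        raise ValueError(f"internal stop codon at codon {where}")
    if syn_p == 0.0 and nonsyn_p == 0.0:
        return cds
    new_idx = idx.copy()
    probs = np.array([syn_p, nonsyn_p, 0.0])
    # per position: categorical draw over {keep, alt0, alt1, alt2}
    chosen = np.full((len(idx), 3), -1, dtype=np.int64)
    for pos in range(3):
        p_alt = probs[cls[idx, pos, :]] / (3.0 - tau[idx, pos])[:, None]
        cum = np.cumsum(p_alt, axis=1)
        u = rng.random(len(idx))
        sel = (u[:, None] < cum).argmax(axis=1)
        hit = u < cum[:, 2]
        chosen[hit, pos] = sel[hit]
    # apply all chosen changes relative to the ancestral codon
    for pos in range(3):
        hit = chosen[:, pos] >= 0
        if hit.any():
            base_shift = 4 ** (2 - pos)
            anc_digit = (idx[hit] // base_shift) % 4
            alt_full = alt_codon[idx[hit], pos, chosen[hit, pos]]
            alt_digit = (alt_full // base_shift) % 4
            new_idx[hit] += (alt_digit - anc_digit) * base_shift
    # combined multi-hit codons can land on a stop even though each single
    # change was stop-free; revert changes right-to-left until sense again
    bad = np.nonzero(is_stop[new_idx])[0]
    for i in bad:
        for pos in (2, 1, 0):
            if chosen[i, pos] >= 0 and is_stop[new_idx[i]]:
                base_shift = 4 ** (2 - pos)
                anc_digit = (idx[i] // base_shift) % 4
                cur_digit = (new_idx[i] // base_shift) % 4
                new_idx[i] += (anc_digit - cur_digit) * base_shift
            if not is_stop[new_idx[i]]:
                break
    return decode_codons(new_idx)


def _random_cds(n_codons: int, rng: np.random.Generator) -> str:
    """Random sense-codon CDS (uniform over the 61 sense codons)."""
    return decode_codons(SENSE_INDEX[rng.integers(0, len(SENSE_INDEX), n_codons)])


def _diverge(cds: str, years: float, mu: float, omega: float,
             rng: np.random.Generator) -> str:
    """Evolve one lineage for `years`: K = mu*years per synonymous site.

    jc_p(mu, t) is the PAIR expectation for a split t years ago (K = 2*mu*t),
    so a single branch of t years uses jc_p(mu, t/2).
    """
    return mutate_sequence(cds, jc_p(mu, years / 2.0),
                           jc_p(omega * mu, years / 2.0), rng)


def simulate_cds_pairs(n_pairs: int, n_codons: int, syn_p: float,
                       nonsyn_p: float, seed: int) -> list[tuple[str, str]]:
    """Independent CDS pairs whose synonymous sites differ with syn_p.

    One ancestral sequence per pair; the partner is a single planted-difference
    draw at the stated class probabilities.
    """
    rng = np.random.default_rng(seed)
    pairs = []
    for _ in range(n_pairs):
        a = _random_cds(n_codons, rng)
        b = mutate_sequence(a, syn_p, nonsyn_p, rng)
        pairs.append((a, b))
    return pairs


# ---------------------------------------------------------------- genome pair


def _layout(genes_in_order: list[tuple[str, str, str]], spacing: dict[str, int],
            default_spacing: int) -> list[GeneModel]:
    """Assign coordinates: fixed intergenic spacing, tandem copies closer."""
    models: list[GeneModel] = []
    by_chrom: dict[str, list[tuple[str, str, str]]] = {}
    for gid, chrom, cds in genes_in_order:
        by_chrom.setdefault(chrom, []).append((gid, chrom, cds))
    for chrom, rows in by_chrom.items():
        pos = default_spacing
        for gid, _, cds in rows:
            start = pos
            end = start + len(cds)
            models.append(GeneModel(gene_id=gid, chromosome=chrom, start=start,
                                    end=end, strand="+", cds=cds))
            pos = end + spacing.get(gid, default_spacing)
    return models


def simulate_genome_pair(scenario: EvolutionScenario
                         ) -> tuple[Genome, Genome, TruthTable]:
    """Evolve an ancestor into two genomes with a complete truth table.

    The history is: ancestor -> (optional shared WGD at wgd_age) -> speciation
    at speciation_age -> per-lineage tandem duplications / inversions ->
    present. True pair divergences are recorded in K = 2*mu*age units at
    synonymous sites.
    """
    sc = scenario
    ss = np.random.SeedSequence(sc.seed)
    rng_seq, rng_events, rng_branch = [np.random.default_rng(s)
                                       for s in ss.spawn(3)]
    mu, omega = sc.syn_rate_mu, sc.omega
    truth = TruthTable()

    # ancestral gene set
    lo, hi = sc.cds_length_codons
    ancestors: list[tuple[str, str]] = []  # (family id, cds)
    for ci in range(sc.n_chromosomes):
        for gi in range(sc.genes_per_chromosome):
            n_cod = int(rng_seq.integers(lo, hi + 1))
            ancestors.append((f"f{ci + 1:02d}g{gi + 1:04d}", _random_cds(n_cod, rng_seq)))

    n_anc = len(ancestors)
    per_chrom = sc.genes_per_chromosome

    # family -> (chromosome index, copy tag); copy 0 on chr 1..n, copy 1 on
    # duplicated chromosomes n+1..2n (shared WGD)
    shared_wgd = sc.wgd_age is not None and sc.wgd_lineage == "shared"

    def chrom_name(ci: int) -> str:
        return f"chr{ci + 1}"

    # ---- shared pre-speciation part
    if shared_wgd:
        wgd_branch = sc.wgd_age - sc.speciation_age
        # duplicate every gene, then apply retention
        total_post = ceil((1.0 - sc.gene_loss_fraction_post_wgd) * 2 * n_anc)
        n_remove = 2 * n_anc - total_post
        dup_ids = np.arange(n_anc)
        if n_remove > n_anc:
            raise ConfigurationError(
                "gene_loss_fraction_post_wgd too high: would delete whole families")
        removed = set(rng_events.choice(dup_ids, size=n_remove, replace=False).tolist())
        truth.rearrangements.append(
            f"wgd\tshared\tage={sc.wgd_age:.6g}\tretained={total_post}")
        # state at speciation: each surviving copy evolved wgd_branch years
        lineage_roots: list[tuple[str, int, int, str]] = []  # family, chrom, copy, cds
        for i, (fam, cds) in enumerate(ancestors):
            ci = i // per_chrom
            c0 = _diverge(cds, wgd_branch, mu, omega, rng_branch)
            lineage_roots.append((fam, ci, 0, c0))
            if i not in removed:
                c1 = _diverge(cds, wgd_branch, mu, omega, rng_branch)
                lineage_roots.append((fam, ci + sc.n_chromosomes, 1, c1))
    else:
        lineage_roots = [(fam, i // per_chrom, 0, cds)
                         for i, (fam, cds) in enumerate(ancestors)]

    # ---- per-lineage evolution
    def evolve_lineage(tag: str) -> list[tuple[str, str, str, float]]:
        """Returns (gene id, chromosome, cds, tandem_template_age) rows."""
        n_chrom_total = sc.n_chromosomes * (2 if shared_wgd else 1)
        rows: list[dict] = []
        for fam, ci, copy, cds in lineage_roots:
            gid = f"{tag}_{fam}" + (f"_w{copy}" if copy else "")
            rows.append({"id": gid, "fam": fam, "copy": copy, "chrom": ci,
                         "cds": cds, "birth": sc.speciation_age})
        # lineage-specific WGD (query-vs-reference depth experiments)
        if sc.wgd_age is not None and sc.wgd_lineage == tag:
            total_post = ceil((1.0 - sc.gene_loss_fraction_post_wgd) * 2 * len(rows))
            n_remove = 2 * len(rows) - total_post
            removed = set(rng_events.choice(np.arange(len(rows)), size=n_remove,
                                            replace=False).tolist())
            truth.rearrangements.append(
                f"wgd\t{tag}\tage={sc.wgd_age:.6g}\tretained={total_post}")
            extra = []
            for i, r in enumerate(rows):
                # evolve both copies from speciation state down to wgd_age
                pre = _diverge(r["cds"], sc.speciation_age - sc.wgd_age, mu,
                               omega, rng_branch)
                r["cds"] = pre
                r["birth"] = sc.wgd_age
                if i not in removed:
                    extra.append({"id": r["id"] + "_w1", "fam": r["fam"],
                                  "copy": 1, "chrom": r["chrom"] + n_chrom_total,
                                  "cds": pre, "birth": sc.wgd_age,
                                  "wgd_sib": r["id"]})
            rows.extend(extra)

        # evolve to present, pausing for tandem events on this lineage
        events = sorted([e for e in sc.tandem_events if e.lineage == tag],
                        key=lambda e: -e.age)
        spacing: dict[str, int] = {}
        order_insert: list[tuple[str, dict]] = []  # (after id, row)
        for r in rows:
            r["t_now"] = r["birth"]
        for ev in events:
            if ev.source_index >= len(rows):
                raise ConfigurationError(
                    f"tandem event source index {ev.source_index} out of range")
            src = rows[ev.source_index]
            # bring the template down to the event time
            src["cds"] = _diverge(src["cds"], src["t_now"] - ev.age, mu, omega,
                                  rng_branch)
            src["t_now"] = ev.age
            for k in range(ev.copies):
                cid = f"{src['id']}_t{k + 1}"
                row = {"id": cid, "fam": src["fam"], "copy": src["copy"],
                       "chrom": src["chrom"], "cds": src["cds"],
                       "birth": ev.age, "t_now": ev.age, "tandem_of": src["id"],
                       "tandem_age": ev.age}
                order_insert.append((src["id"], row))
                spacing[cid] = ev.spacing_bp
                truth.rearrangements.append(
                    f"tandem\t{tag}\tage={ev.age:.6g}\tsource={src['id']}\tcopy={cid}")
        for r in rows:
            r["cds"] = _diverge(r["cds"], r["t_now"], mu, omega, rng_branch)
            r["t_now"] = 0.0
        for after_id, row in order_insert:
            row["cds"] = _diverge(row["cds"], row["t_now"], mu, omega, rng_branch)
            row["t_now"] = 0.0
            i = next(j for j, r in enumerate(rows) if r["id"] == after_id)
            rows.insert(i + 1, row)
        # inversions: reverse gene order within the span
        for ev in sc.inversion_events:
            if ev.lineage != tag:
                continue
            on_chrom = [j for j, r in enumerate(rows)
                        if chrom_name(r["chrom"]) == ev.chromosome]
            lo_i, hi_i = ev.span
            sel = on_chrom[lo_i:hi_i]
            if not sel:
                raise ConfigurationError(
                    f"inversion span {ev.span} empty on {ev.chromosome} ({tag})")
            segment = [rows[j] for j in sel]
            for j, r in zip(sel, reversed(segment)):
                rows[j] = r
            truth.rearrangements.append(
                f"inversion\t{tag}\t{ev.chromosome}\tspan={lo_i}-{hi_i}")
        ordered = [(r["id"], chrom_name(r["chrom"]), r["cds"]) for r in rows]
        models = _layout(ordered, spacing, sc.intergenic_bp)
        # truth bookkeeping
        for r in rows:
            truth.gene_history[r["id"]] = (
                f"lineage={tag};family={r['fam']};copy={r['copy']};"
                f"birth={r['birth']:.6g}")
            if "tandem_of" in r:
                truth.paralog_pairs.append(
                    (tag, r["tandem_of"], r["id"], "tandem", r["tandem_age"],
                     2.0 * mu * r["tandem_age"]))
            if "wgd_sib" in r:
                truth.paralog_pairs.append(
                    (tag, r["wgd_sib"], r["id"], "wgd", sc.wgd_age,
                     2.0 * mu * sc.wgd_age))
        return models, rows

    models_a, rows_a = evolve_lineage("A")
    models_b, rows_b = evolve_lineage("B")

    # ortholog truth: same family+copy across lineages
    b_index = {(r["fam"], r["copy"]): r["id"] for r in rows_b
               if "tandem_of" not in r}
    for r in rows_a:
        if "tandem_of" in r:
            continue
        partner = b_index.get((r["fam"], r["copy"]))
        if partner is not None:
            truth.ortholog_pairs.append(
                (r["id"], partner, 2.0 * mu * sc.speciation_age))
    # shared-WGD paralog truth (both lineages)
    if shared_wgd:
        for tag, rows in (("A", rows_a), ("B", rows_b)):
            copies: dict[str, dict[int, str]] = {}
            for r in rows:
                if "tandem_of" in r:
                    continue
                copies.setdefault(r["fam"], {})[r["copy"]] = r["id"]
            for fam, cc in sorted(copies.items()):
                if 0 in cc and 1 in cc:
                    truth.paralog_pairs.append(
                        (tag, cc[0], cc[1], "wgd", sc.wgd_age,
                         2.0 * mu * sc.wgd_age))

    n_chrom_a = sc.n_chromosomes * (2 if shared_wgd or sc.wgd_lineage == "A"
                                    and sc.wgd_age is not None else 1)
    n_chrom_b = sc.n_chromosomes * (2 if shared_wgd or sc.wgd_lineage == "B"
                                    and sc.wgd_age is not None else 1)
    genome_a = Genome("speciesA", models_a, [f"chr{i + 1}" for i in range(n_chrom_a)])
    genome_b = Genome("speciesB", models_b, [f"chr{i + 1}" for i in range(n_chrom_b)])
    return genome_a, genome_b, truth


def chromosome_sequences(genome: Genome, rng_or_seed=0) -> dict[str, str]:
    """Embed gene CDS into random intergenic background, honouring coordinates."""
    rng = np.random.default_rng(rng_or_seed) if isinstance(rng_or_seed, (int, np.integer)) \
        else rng_or_seed
    out: dict[str, str] = {}
    for chrom in genome.chromosomes:
        genes = genome.genes_on(chrom)
        if not genes:
            continue
        length = max(g.end for g in genes) + 1000
        arr = rng.integers(0, 4, length)
        seq = np.array(list("ACGT"))[arr]
        for g in genes:
            seq[g.start:g.end] = list(g.cds)
        out[chrom] = "".join(seq)
    return out


# ---------------------------------------------------------------- LTR


def simulate_ltr_pairs(n: int, length: int, p: float, seed: int
                       ) -> list[tuple[str, str]]:
    """n repeat pairs whose sites independently differ with probability p."""
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    out = []
    for _ in range(n):
        anc = rng.integers(0, 4, length)
        flip = rng.random(length) < p
        shift = rng.integers(1, 4, length)
        der = np.where(flip, (anc + shift) % 4, anc)
        out.append(("".join(bases[anc]), "".join(bases[der])))
    return out


def simulate_ltr_set(n: int, length: int, age: float, mu: float, seed: int
                     ) -> list[LTRElementSim]:
    """Full-length LTR elements whose terminal repeats diverged for `age` years.

    Per-site difference probability between the two repeats is
    3/4 (1 - exp(-8 mu age / 3)), the JC expectation for K = 2 mu age.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if length < 100:
        raise ValueError("LTR length must be >= 100 bp")
    p = jc_p(mu, age)
    pairs = simulate_ltr_pairs(n, length, p, seed)
    elements = []
    pos = 10_000
    for i, (l5, l3) in enumerate(pairs):
        start = pos
        end = start + 2 * length + 5000  # internal region placeholder span
        elements.append(LTRElementSim(element_id=f"ltr{i + 1:05d}", chromosome="chr1",
                                      start=start, end=end, ltr5_seq=l5,
                                      ltr3_seq=l3, true_age=age))
        pos = end + 1000
    return elements


# ---------------------------------------------------------------- Hi-C plaid


@dataclass
class PlaidConfig:
    """Plaid (checkerboard) Hi-C contact-matrix generator settings.

    The expected count is scale * (1+|i-j|)^(-decay) * (1 + s*c_i*c_j) with
    compartment signs c in {+1 (A), -1 (B)}; observed counts are Poisson
    unless noise=False. Gene/TE densities per bin are Poisson with
    compartment-specific means (A gene-dense, B TE-rich).
    """

    n_bins: int = 500
    bin_size: int = 100_000
    fraction_A: float = 0.532
    decay_exponent: float = 1.0
    plaid_strength: float = 0.4
    noise_scale: float = 100.0
    noise: bool = True
    gene_density_A: float = 12.0
    gene_density_B: float = 4.0
    te_density_A: float = 20.0
    te_density_B: float = 55.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.fraction_A < 1.0:
            raise ValueError("fraction_A must be in (0, 1)")
        if self.plaid_strength >= 1.0 or self.plaid_strength < 0.0:
            raise ValueError("plaid_strength must be in [0, 1) "
                             "(negative expected counts otherwise)")
        if self.gene_density_A <= self.gene_density_B:
            raise ValueError("gene_density_A must exceed gene_density_B")
        if self.te_density_B <= self.te_density_A:
            raise ValueError("te_density_B must exceed te_density_A")


def simulate_contact_matrix(cfg: PlaidConfig):
    """Returns (ContactMatrix, labels, gene_density, te_density).

    labels is an array of 'A'/'B' truth calls; exactly
    round(fraction_A * n_bins) bins are A.
    """
    from .compartments import ContactMatrix  # local import to avoid a cycle

    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_bins
    n_a = int(round(cfg.fraction_A * n))
    labels = np.array(["B"] * n, dtype=object)
    a_bins = rng.permutation(n)[:n_a]
    labels[a_bins] = "A"
    c = np.where(labels == "A", 1.0, -1.0)
    i = np.arange(n)
    dist = np.abs(i[:, None] - i[None, :])
    expected = (cfg.noise_scale * (1.0 + dist) ** (-cfg.decay_exponent)
                * (1.0 + cfg.plaid_strength * np.outer(c, c)))
    if cfg.noise:
        upper = rng.poisson(np.triu(expected))
        counts = np.triu(upper, 1) + np.triu(upper, 1).T + np.diag(np.diag(upper))
        counts = counts.astype(float)
    else:
        counts = expected.copy()
    is_a = labels == "A"
    gene_density = np.where(is_a, rng.poisson(cfg.gene_density_A, n),
                            rng.poisson(cfg.gene_density_B, n)).astype(float)
    te_density = np.where(is_a, rng.poisson(cfg.te_density_A, n),
                          rng.poisson(cfg.te_density_B, n)).astype(float)
    if not cfg.noise:
        gene_density = np.where(is_a, cfg.gene_density_A, cfg.gene_density_B)
        te_density = np.where(is_a, cfg.te_density_A, cfg.te_density_B)
    bins = [("chr1", k * cfg.bin_size, (k + 1) * cfg.bin_size) for k in range(n)]
    return ContactMatrix(bins=bins, counts=counts), labels, gene_density, te_density
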
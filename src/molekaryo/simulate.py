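"""Synthetic parental genomes, meiosis, conceptus construction and rendering.

The generator emulates the data a molecular-diagnostics lab sees for a
hydatidiform-mole workup: a SNP-array duo (mole villous sample plus the
patient's blood) and a 16-locus STR profile for each.  Parents are drawn
from population allele frequencies, gametes are produced by a Poisson
crossover model, and conceptuses are assembled according to a
:class:`ConstitutionSpec` — monospermic (one sperm endoreduplicated, fully
homozygous) or dispermic (two independent sperm, segmentally homozygous)
androgenetic moles, biparental diploids, and diandric or digynic triploids,
optionally with extra maternal/paternal chromosomes or biparental disomies
injected on named autosomes.  The mitochondrial genotype is always copied
from the mother.

Rendering converts the true homolog multiset at each locus into array
observables: for copy number n with k B alleles the ideal BAF is k/n and
the ideal LRR is attenuation × log2(n/2); Gaussian noise is added and BAF
is clipped to [0, 1].  Genotype calls (GType) come from the true allele
multiset, with a configurable no-call rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, DataError
from .panel import (
    AUTOSOMES,
    GeneticMap,
    LocusPanel,
    StrPanel,
    default_genetic_map,
    default_panel,
    default_str_panel,
)
from .sample import SnpArraySample, StrProfile, allele_sort_key

ANDROGENETIC_MODES = ("monospermic_CHM", "dispermic_CHM")
MODES = ANDROGENETIC_MODES + ("biparental_diploid", "diandric_triploid_PHM", "digynic_triploid")

#: LRR rendered at Y loci when the conceptus carries no Y chromosome.
NULL_Y_LRR = -3.0


@dataclass(frozen=True)
class NoiseModel:
    """Array noise: additive Gaussian on BAF and LRR, multiplicative LRR
    attenuation (real platforms compress LRR toward 0), and a no-call rate."""

    baf_sd: float = 0.03
    lrr_sd: float = 0.15
    lrr_attenuation: float = 1.0
    missing_rate: float = 0.005

    def __post_init__(self) -> None:
        if self.baf_sd < 0 or self.lrr_sd < 0:
            raise ConfigError("noise SDs must be >= 0")
        if not 0 <= self.missing_rate < 1:
            raise ConfigError("missing_rate must be in [0, 1)")
        if not 0 < self.lrr_attenuation <= 1:
            raise ConfigError("lrr_attenuation must be in (0, 1]")


NOISE_FREE = NoiseModel(baf_sd=0.0, lrr_sd=0.0, missing_rate=0.0)


@dataclass
class ParentalGenomes:
    """Phased parental haplotypes over a locus panel (True = B allele).

    The father carries two haplotypes per autosome plus one X and one Y;
    the mother two per autosome, two X, and one mitochondrial haplotype.
    Each parental haplotype also carries one allele per autosomal STR locus,
    assigned at creation so that STR inheritance follows the SNP haplotype
    a gamete carries at the STR's position.
    """

    panel: LocusPanel
    str_panel: StrPanel
    father_auto: dict[str, np.ndarray]
    father_x: np.ndarray
    father_y: np.ndarray
    mother_auto: dict[str, np.ndarray]
    mother_x: np.ndarray
    mother_mt: np.ndarray
    father_str: dict[str, tuple[str, str]]
    mother_str: dict[str, tuple[str, str]]


def simulate_parents(
    panel: LocusPanel,
    seed: int | np.random.SeedSequence,
    str_panel: StrPanel | None = None,
) -> ParentalGenomes:
    """Draw a mother and a father from the panel's population frequencies.

    Every allele on every haplotype is an independent Bernoulli draw with
    the locus's population B-allele frequency; STR alleles are drawn from
    the STR panel's allele frequency tables, one per haplotype.
    """
    str_panel = str_panel or default_str_panel()
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)

    def draw(chrom: str, n_hap: int) -> np.ndarray:
        f = panel.freqs(chrom)
        return rng.random((n_hap, f.size)) < f

    father_auto = {c: draw(c, 2) for c in AUTOSOMES}
    mother_auto = {c: draw(c, 2) for c in AUTOSOMES}
    father_x = draw("X", 1)[0]
    father_y = draw("Y", 1)[0]
    mother_x = draw("X", 2)
    mother_mt = draw("MT", 1)[0]

    def draw_str() -> dict[str, tuple[str, str]]:
        out = {}
        for locus in str_panel.autosomal():
            picks = rng.choice(len(locus.alleles), size=2, p=np.asarray(locus.freqs))
            out[locus.name] = (locus.alleles[picks[0]], locus.alleles[picks[1]])
        return out

    return ParentalGenomes(
        panel=panel, str_panel=str_panel,
        father_auto=father_auto, father_x=father_x, father_y=father_y,
        mother_auto=mother_auto, mother_x=mother_x, mother_mt=mother_mt,
        father_str=draw_str(), mother_str=draw_str(),
    )


@dataclass(frozen=True)
class GameteChrom:
    """One transmitted chromosome: alleles plus per-locus source haplotype."""

    alleles: np.ndarray
    source: np.ndarray  # 0/1 parental haplotype index per locus


def _meiosis(haplotypes: np.ndarray, genetic_pos: np.ndarray,
             morgans: float, rng: np.random.Generator) -> GameteChrom:
    """Poisson crossover model: crossover count ~ Poisson(genetic length),
    crossover genetic positions uniform, starting haplotype uniform."""
    if haplotypes.ndim != 2 or haplotypes.shape[0] != 2:
        raise ConfigError("meiosis needs exactly two parental haplotypes")
    n = haplotypes.shape[1]
    start = int(rng.integers(2))
    if morgans <= 0:
        source = np.full(n, start, dtype=np.int8)
    else:
        k = rng.poisson(morgans)
        cuts = np.sort(rng.uniform(0.0, morgans, size=k))
        source = ((start + np.searchsorted(cuts, genetic_pos)) % 2).astype(np.int8)
    return GameteChrom(haplotypes[source, np.arange(n)], source)


def simulate_gamete(
    parent_haplotypes: dict[str, np.ndarray],
    panel: LocusPanel,
    genetic_map: GeneticMap,
    seed: int | np.random.SeedSequence | np.random.Generator,
) -> dict[str, GameteChrom]:
    """Run one meiosis per chromosome in ``parent_haplotypes``.

    Each value must be a (2, n_loci) haplotype pair for a recombining
    chromosome of the panel; returns the transmitted chromosome and the
    per-locus source haplotype.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = {}
    for chrom, haps in parent_haplotypes.items():
        gpos = genetic_map.genetic_position(chrom, panel.positions(chrom))
        out[chrom] = _meiosis(np.asarray(haps), gpos, genetic_map.length(chrom), rng)
    return out


@dataclass(frozen=True)
class Gamete:
    """A full gamete: autosomal chromosomes, sex-chromosome content and the
    STR alleles it transmits (tied to the SNP haplotype at each STR locus)."""

    autosomes: dict[str, GameteChrom]
    x: np.ndarray | None
    y: np.ndarray | None
    sex_content: str
    strs: dict[str, str]


def _str_alleles_from_sources(parents_str: dict[str, tuple[str, str]],
                              autosomes: dict[str, GameteChrom],
                              panel: LocusPanel, str_panel: StrPanel) -> dict[str, str]:
    out = {}
    for locus in str_panel.autosomal():
        chrom_pos = panel.positions(locus.chrom)
        idx = min(int(np.searchsorted(chrom_pos, locus.position)), chrom_pos.size - 1)
        hap = int(autosomes[locus.chrom].source[idx])
        out[locus.name] = parents_str[locus.name][hap]
    return out


def _sperm(parents: ParentalGenomes, sex_content: str, gmap: GeneticMap,
           rng: np.random.Generator) -> Gamete:
    autos = simulate_gamete(parents.father_auto, parents.panel, gmap, rng)
    if sex_content not in ("X", "Y", "XY"):
        raise ConfigError(f"invalid sperm sex content {sex_content!r}")
    return Gamete(
        autosomes=autos,
        x=parents.father_x.copy() if "X" in sex_content else None,
        y=parents.father_y.copy() if "Y" in sex_content else None,
        sex_content=sex_content,
        strs=_str_alleles_from_sources(parents.father_str, autos,
                                       parents.panel, parents.str_panel),
    )


def _egg(parents: ParentalGenomes, gmap: GeneticMap, rng: np.random.Generator) -> Gamete:
    autos = simulate_gamete(parents.mother_auto, parents.panel, gmap, rng)
    gpos = gmap.genetic_position("X", parents.panel.positions("X"))
    x = _meiosis(parents.mother_x, gpos, gmap.length("X"), rng)
    return Gamete(
        autosomes=autos, x=x.alleles, y=None, sex_content="X",
        strs=_str_alleles_from_sources(parents.mother_str, autos,
                                       parents.panel, parents.str_panel),
    )


@dataclass(frozen=True)
class ConstitutionSpec:
    """Requested genetic constitution of a conceptus.

    ``extra_chromosomes`` lists (autosome, origin) trisomy injections;
    ``biparental_disomies`` lists autosomes where one paternal homolog is
    replaced by a maternal one (only meaningful inside androgenetic modes).
    """

    mode: str
    sex: str = "XX"
    extra_chromosomes: tuple[tuple[str, str], ...] = ()
    biparental_disomies: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ConfigError(f"unknown constitution mode {self.mode!r}")
        for chrom, origin in self.extra_chromosomes:
            if chrom not in AUTOSOMES:
                raise ConfigError(f"extra chromosome must be autosomal, got {chrom!r}")
            if origin not in ("maternal", "paternal"):
                raise ConfigError(f"extra-chromosome origin must be maternal/paternal")
        for chrom in self.biparental_disomies:
            if chrom not in AUTOSOMES:
                raise ConfigError(f"biparental disomy must be autosomal, got {chrom!r}")
        if self.biparental_disomies and self.mode not in ANDROGENETIC_MODES:
            raise ConfigError("biparental disomies only apply to androgenetic modes")
        self._gamete_plan()  # validates sex constitution for the mode

    def _gamete_plan(self) -> tuple[list[str], int]:
        """Return (sperm sex contents, number of eggs) realizing ``sex``."""
        mode, sex = self.mode, self.sex
        if mode == "monospermic_CHM":
            plans = {"XX": (["X"], 0), "XXYY": (["XY"], 0)}
        elif mode == "dispermic_CHM":
            plans = {"XX": (["X", "X"], 0), "XY": (["X", "Y"], 0),
                     "XYY": (["XY", "Y"], 0), "XXYY": (["XY", "XY"], 0)}
        elif mode == "biparental_diploid":
            plans = {"XX": (["X"], 1), "XY": (["Y"], 1)}
        elif mode == "diandric_triploid_PHM":
            plans = {"XXX": (["X", "X"], 1), "XXY": (["X", "Y"], 1),
                     "XYY": (["Y", "Y"], 1)}
        else:  # digynic_triploid
            plans = {"XXX": (["X"], 2), "XXY": (["Y"], 2)}
        if sex not in plans:
            raise ConfigError(f"sex constitution {sex!r} not realizable in mode {mode!r}")
        return plans[sex]


@dataclass(frozen=True)
class Homolog:
    """One homolog of a conceptus chromosome, tagged with its parental
    origin, the index of the gamete that contributed it, and the STR
    alleles it carries for STR loci on that chromosome."""

    alleles: np.ndarray
    origin: str  # "maternal" | "paternal"
    gamete: int
    str_alleles: dict[str, str] = field(default_factory=dict)


@dataclass
class ConceptusGenome:
    """Simulation truth: the full homolog content of one conceptus."""

    panel: LocusPanel
    str_panel: StrPanel
    autosomes: dict[str, list[Homolog]]
    x: list[Homolog]
    y: list[Homolog]
    mt: np.ndarray
    sex_truth: str
    spec: ConstitutionSpec | None = None

    def copy_number(self, chrom: str) -> int:
        if chrom == "X":
            return len(self.x)
        if chrom == "Y":
            return len(self.y)
        if chrom == "MT":
            return 1
        return len(self.autosomes[chrom])

    def origins(self, chrom: str) -> list[str]:
        return [h.origin for h in self.autosomes[chrom]]

    def has_maternal(self, chrom: str) -> bool:
        return "maternal" in self.origins(chrom)

    def n_het_loci(self, chrom: str) -> int:
        stack = np.stack([h.alleles for h in self.autosomes[chrom]])
        k = stack.sum(axis=0)
        return int(np.sum((k > 0) & (k < stack.shape[0])))


def _homologs_from_gamete(gam: Gamete, gamete_idx: int, origin: str,
                          str_panel: StrPanel) -> dict[str, Homolog]:
    by_chrom_strs: dict[str, dict[str, str]] = {}
    for locus in str_panel.autosomal():
        by_chrom_strs.setdefault(locus.chrom, {})[locus.name] = gam.strs[locus.name]
    return {
        chrom: Homolog(gc.alleles.copy(), origin, gamete_idx,
                       by_chrom_strs.get(chrom, {}))
        for chrom, gc in gam.autosomes.items()
    }


def construct_conceptus(
    spec: ConstitutionSpec,
    parents: ParentalGenomes,
    seed: int | np.random.SeedSequence,
    genetic_map: GeneticMap | None = None,
) -> ConceptusGenome:
    """Assemble a conceptus from gametes according to ``spec``.

    Monospermic moles duplicate a single sperm (fully homozygous);
    dispermic moles combine two independent sperm from the same father
    (segmentally homozygous wherever the two sperm carry the same paternal
    haplotype).  Triploid modes add an egg or a second egg.  Extra
    chromosomes and biparental disomies are injected per autosome from
    additional independent meioses.  The mitochondrial haplotype is always
    the mother's.
    """
    gmap = genetic_map or default_genetic_map()
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)

    sperm_contents, n_eggs = spec._gamete_plan()
    gametes: list[tuple[Gamete, str]] = []  # (gamete, origin)
    for content in sperm_contents:
        gametes.append((_sperm(parents, content, gmap, rng), "paternal"))
    for _ in range(n_eggs):
        gametes.append((_egg(parents, gmap, rng), "maternal"))

    if spec.mode == "monospermic_CHM":
        gametes = [gametes[0], gametes[0]]  # endoreduplication of the one sperm

    autosomes: dict[str, list[Homolog]] = {c: [] for c in AUTOSOMES}
    x: list[Homolog] = []
    y: list[Homolog] = []
    for idx, (gam, origin) in enumerate(gametes):
        per_chrom = _homologs_from_gamete(gam, idx, origin, parents.str_panel)
        for chrom, hom in per_chrom.items():
            autosomes[chrom].append(hom)
        if gam.x is not None:
            x.append(Homolog(gam.x.copy(), origin, idx))
        if gam.y is not None:
            y.append(Homolog(gam.y.copy(), origin, idx))

    def extra_homolog(chrom: str, origin: str, gamete_idx: int) -> Homolog:
        src_haps = parents.mother_auto if origin == "maternal" else parents.father_auto
        src_strs = parents.mother_str if origin == "maternal" else parents.father_str
        gpos = gmap.genetic_position(chrom, parents.panel.positions(chrom))
        gc = _meiosis(src_haps[chrom], gpos, gmap.length(chrom), rng)
        strs = {}
        for locus in parents.str_panel.autosomal():
            if locus.chrom != chrom:
                continue
            pos = parents.panel.positions(chrom)
            i = min(int(np.searchsorted(pos, locus.position)), pos.size - 1)
            strs[locus.name] = src_strs[locus.name][int(gc.source[i])]
        return Homolog(gc.alleles, origin, gamete_idx, strs)

    next_idx = len(gametes)
    for chrom, origin in spec.extra_chromosomes:
        autosomes[chrom].append(extra_homolog(chrom, origin, next_idx))
        next_idx += 1
    for chrom in spec.biparental_disomies:
        pat = [i for i, h in enumerate(autosomes[chrom]) if h.origin == "paternal"]
        if not pat:
            raise ConfigError(f"no paternal homolog to replace on chromosome {chrom}")
        autosomes[chrom][pat[0]] = extra_homolog(chrom, "maternal", next_idx)
        next_idx += 1

    return ConceptusGenome(
        panel=parents.panel, str_panel=parents.str_panel,
        autosomes=autosomes, x=x, y=y,
        mt=parents.mother_mt.copy(), sex_truth=spec.sex, spec=spec,
    )


def maternal_reference_genome(parents: ParentalGenomes) -> ConceptusGenome:
    """The mother's own genome packaged like a conceptus, for rendering the
    patient blood sample of a duo."""
    autosomes = {}
    for chrom in AUTOSOMES:
        homs = []
        for i in range(2):
            strs = {l.name: parents.mother_str[l.name][i]
                    for l in parents.str_panel.autosomal() if l.chrom == chrom}
            homs.append(Homolog(parents.mother_auto[chrom][i].copy(), "maternal", -1, strs))
        autosomes[chrom] = homs
    x = [Homolog(parents.mother_x[i].copy(), "maternal", -1) for i in range(2)]
    return ConceptusGenome(
        panel=parents.panel, str_panel=parents.str_panel,
        autosomes=autosomes, x=x, y=[],
        mt=parents.mother_mt.copy(), sex_truth="XX", spec=None,
    )


def render_array(
    genome: ConceptusGenome,
    noise: NoiseModel,
    seed: int | np.random.SeedSequence,
    sample_id: str = "SAMPLE",
) -> SnpArraySample:
    """Render a conceptus (or maternal reference) genome into array records.

    Ideal BAF at a locus with k B alleles out of n homologs is k/n; ideal
    LRR is attenuation × log2(n/2).  Genotype calls come from the true
    allele multiset (all-A → AA, all-B → BB, mixed → AB).  Y loci in a
    conceptus without a Y chromosome are rendered as no-calls with LRR near
    −3 and uninformative BAF; mitochondrial loci are rendered at the
    maternal haplotype with LRR near 0.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    panel = genome.panel
    att = noise.lrr_attenuation

    cols: dict[str, list[np.ndarray]] = {k: [] for k in
                                         ("snp_name", "chrom", "position",
                                          "gtype", "baf", "lrr")}
    for chrom in panel.chromosomes:
        n = panel.n_loci(chrom)
        if chrom == "MT":
            k = genome.mt.astype(float)
            baf_true, lrr_true = k, np.zeros(n)
            gtype = np.where(genome.mt, "BB", "AA")
        elif chrom == "Y" and not genome.y:
            baf_true = rng.uniform(0.0, 1.0, size=n)
            lrr_true = np.full(n, NULL_Y_LRR)
            gtype = np.full(n, "NC")
        else:
            homs = (genome.autosomes[chrom] if chrom in AUTOSOMES
                    else (genome.x if chrom == "X" else genome.y))
            stack = np.stack([h.alleles for h in homs])
            m = stack.shape[0]
            k = stack.sum(axis=0)
            baf_true = k / m
            lrr_true = np.full(n, att * math.log2(m / 2))
            gtype = np.where(k == 0, "AA", np.where(k == m, "BB", "AB"))

        baf = np.clip(baf_true + rng.normal(0.0, noise.baf_sd, size=n), 0.0, 1.0) \
            if noise.baf_sd > 0 else np.asarray(baf_true, dtype=float)
        lrr = lrr_true + (rng.normal(0.0, noise.lrr_sd, size=n) if noise.lrr_sd > 0 else 0.0)
        if noise.missing_rate > 0:
            gtype = np.where(rng.random(n) < noise.missing_rate, "NC", gtype)

        cols["snp_name"].append(panel.ids(chrom))
        cols["chrom"].append(np.full(n, chrom, dtype=object))
        cols["position"].append(panel.positions(chrom))
        cols["gtype"].append(np.asarray(gtype, dtype=object))
        cols["baf"].append(np.round(baf, 4))
        cols["lrr"].append(np.round(np.asarray(lrr, dtype=float), 4))
    table = pd.DataFrame({k: np.concatenate(v) for k, v in cols.items()})
    return SnpArraySample(sample_id, table)


def render_str(genome: ConceptusGenome, seed: int = 0,
               sample_id: str = "SAMPLE") -> StrProfile:
    """Derive the STR allele-set profile from the homolog content.

    Each homolog contributes one allele per STR locus on its chromosome;
    the profile shows the set of distinct alleles.  The sex marker reports
    X and, if any Y homolog is present, Y.  (``seed`` is accepted for
    interface uniformity; the profile is a pure function of the genome.)
    """
    alleles: dict[str, tuple[str, ...]] = {}
    for locus in genome.str_panel.autosomal():
        obs = {h.str_alleles[locus.name] for h in genome.autosomes[locus.chrom]}
        alleles[locus.name] = tuple(sorted(obs, key=allele_sort_key))
    sex = ["X"] if genome.x else []
    if genome.y:
        sex.append("Y")
    if not sex:
        sex = ["X"]  # degenerate; a conceptus without sex chromosomes is not modelled
    alleles[genome.str_panel.sex_marker] = tuple(sex)
    return StrProfile(sample_id, alleles)


@dataclass(frozen=True)
class CaseSpec:
    """One cohort entry: a case identifier, the constitution to simulate
    and the recorded post-molar outcome (SR = spontaneous remission,
    GTN = gestational trophoblastic neoplasia)."""

    case_id: str
    constitution: ConstitutionSpec
    outcome: str = "SR"


@dataclass
class SimulatedCase:
    """A rendered duo with its generating truth."""

    case_id: str
    spec: ConstitutionSpec
    outcome: str
    truth: ConceptusGenome
    mole_array: SnpArraySample
    maternal_array: SnpArraySample
    mole_str: StrProfile
    maternal_str: StrProfile


def simulate_cohort(
    case_specs: list[CaseSpec],
    seed: int | np.random.SeedSequence,
    panel: LocusPanel | None = None,
    str_panel: StrPanel | None = None,
    genetic_map: GeneticMap | None = None,
    noise: NoiseModel | None = None,
) -> list[SimulatedCase]:
    """Simulate one duo per case spec, with independent parents per case.

    A single root seed is split hierarchically (per case, then per stage),
    so the whole cohort is reproducible and cases are independent.
    """
    panel = panel or default_panel()
    str_panel = str_panel or default_str_panel()
    gmap = genetic_map or default_genetic_map()
    noise = noise if noise is not None else NoiseModel()
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)

    cases = []
    for case, case_ss in zip(case_specs, root.spawn(len(case_specs))):
        s_parents, s_conc, s_mole, s_mat = case_ss.spawn(4)
        parents = simulate_parents(panel, s_parents, str_panel)
        truth = construct_conceptus(case.constitution, parents, s_conc, gmap)
        mother = maternal_reference_genome(parents)
        mole_id = f"{case.case_id}_MOLE"
        mat_id = f"{case.case_id}_BLOOD"
        cases.append(SimulatedCase(
            case_id=case.case_id, spec=case.constitution, outcome=case.outcome,
            truth=truth,
            mole_array=render_array(truth, noise, s_mole, mole_id),
            maternal_array=render_array(mother, noise, s_mat, mat_id),
            mole_str=render_str(truth, sample_id=mole_id),
            maternal_str=render_str(mother, sample_id=mat_id),
        ))
    return cases


def load_cohort_spec(path) -> list[CaseSpec]:
    """Read a cohort specification from YAML.

    Layout::

        cases:
          - id: HM01
            mode: dispermic_CHM
            sex: XY
            extra_chromosomes: [{chromosome: "13", origin: maternal}]
            biparental_disomies: ["6"]
            outcome: SR
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "cases" not in doc:
        raise ConfigError("cohort spec must be a mapping with a 'cases' list")
    specs = []
    for entry in doc["cases"] or []:
        try:
            spec = ConstitutionSpec(
                mode=entry["mode"],
                sex=str(entry.get("sex", "XX")),
                extra_chromosomes=tuple(
                    (str(e["chromosome"]), e["origin"])
                    for e in entry.get("extra_chromosomes", [])),
                biparental_disomies=tuple(
                    str(c) for c in entry.get("biparental_disomies", [])),
            )
        except KeyError as exc:
            raise ConfigError(f"cohort entry {entry.get('id', '?')}: missing {exc}") from exc
        specs.append(CaseSpec(case_id=str(entry["id"]), constitution=spec,
                              outcome=str(entry.get("outcome", "SR"))))
    ids = [c.case_id for c in specs]
    if len(set(ids)) != len(ids):
        raise ConfigError("duplicate case ids in cohort spec")
    return specs


def default_cohort_specs() -> list[CaseSpec]:
    """The packaged 31-case dispermic-CHM reference cohort."""
    from importlib.resources import files

    return load_cohort_spec(files("molekaryo.data") / "default_cohort.yaml")
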
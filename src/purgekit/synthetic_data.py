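"""Synthetic diploid cohorts with full ground truth.

Generates genotype matrices, per-site effect classes, outgroup alleles,
implanted autozygous (ROH) tracts and genotype missingness for two (or more)
populations with distinct demographic histories, standing in for a real
resequencing cohort so that every downstream load statistic can be validated
against known truth.  Also hosts the record- and site-level filters of the
variant QC stage (GATK-style hard filters, MAF/missingness filter, LD
pruning) and plain-text VCF 4.2 round-trip I/O.

Coordinates are 1-based inclusive in the VCF and in all truth tables;
internal arithmetic uses the same convention throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .purging_model import DemographicTrajectory, SelectionClass
from .wf_simulator import simulate_diploid_cohort

__all__ = [
    "PopulationConfig",
    "CohortConfig",
    "CohortDataset",
    "default_config",
    "generate_cohort",
    "implant_roh",
    "write_vcf",
    "read_vcf",
    "HARD_FILTER_THRESHOLDS",
    "apply_hard_filters",
    "site_filters",
    "ld_prune",
]

_BASES = np.array(["A", "C", "G", "T"])
_MISSING = "."


@dataclass
class PopulationConfig:
    """One cohort: a species label with a demographic history and ROH targets.

    ``inbreeding`` is the cohort's realized inbreeding coefficient F: it is
    both the selection-side exposure of recessives in the frequency simulator
    and (via the ROH targets, which should match it) the genotype-side
    autozygosity.
    """

    species: str
    n_individuals: int
    n_populations: int
    trajectory: DemographicTrajectory
    roh_target_mean: float
    roh_target_sd: float
    inbreeding: float = 0.0

    def to_dict(self) -> dict:
        return {
            "species": self.species,
            "n_individuals": self.n_individuals,
            "n_populations": self.n_populations,
            "trajectory": [list(e) for e in self.trajectory.epochs],
            "roh_target_mean": self.roh_target_mean,
            "roh_target_sd": self.roh_target_sd,
            "inbreeding": self.inbreeding,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PopulationConfig":
        d = dict(d)
        d["trajectory"] = DemographicTrajectory(d["trajectory"])
        return cls(**d)


@dataclass
class CohortConfig:
    """Study design of a synthetic cohort.

    Defaults emulate the layout of a rare/widespread conifer pair: a
    bottlenecked cohort of 32 individuals from 9 populations versus a
    large-N cohort of 51 individuals from 17 populations, sharing one
    ancestral equilibrium; a desk-scale genome of 4 x 25 Mb contigs; four
    effect classes with fixed (s, h); and per-individual ROH targets drawn
    around the two species' genome-wide F_ROH means.
    """

    contigs: list = field(default_factory=list)  # [(name, length_bp)]
    class_params: dict = field(default_factory=dict)  # name -> SelectionClass
    class_budgets: dict = field(default_factory=dict)  # name -> mutational origins
    populations: list = field(default_factory=list)  # [PopulationConfig]
    missing_rate: float = 0.02
    outgroup_divergence: float = 0.05
    outgroup_missing_rate: float = 0.02
    roh_min_length: int = 100_000
    roh_mean_extra_length: float = 200_000.0
    roh_het_error: float = 0.001
    roh_purging_generations: float = 20.0

    def to_dict(self) -> dict:
        return {
            "contigs": [list(c) for c in self.contigs],
            "class_params": {
                k: [v.s, v.h, v.lam] for k, v in sorted(self.class_params.items())
            },
            "class_budgets": dict(sorted(self.class_budgets.items())),
            "populations": [p.to_dict() for p in self.populations],
            "missing_rate": self.missing_rate,
            "outgroup_divergence": self.outgroup_divergence,
            "outgroup_missing_rate": self.outgroup_missing_rate,
            "roh_min_length": self.roh_min_length,
            "roh_mean_extra_length": self.roh_mean_extra_length,
            "roh_het_error": self.roh_het_error,
            "roh_purging_generations": self.roh_purging_generations,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        d["contigs"] = [tuple(c) for c in d["contigs"]]
        d["class_params"] = {
            k: SelectionClass(*v) for k, v in d["class_params"].items()
        }
        d["populations"] = [PopulationConfig.from_dict(p) for p in d["populations"]]
        return cls(**d)


def default_config(scale: float = 1.0) -> CohortConfig:
    """The default two-cohort study design (see module docstring).

    ``scale`` < 1 shrinks contig lengths and site budgets proportionally for
    quick runs; statistics are per-base normalized so scale does not affect
    correctness, only precision.
    """
    contig_len = int(25_000_000 * scale)
    budgets = {
        "synonymous": int(150_000 * scale),
        "tolerated": int(40_000 * scale),
        "deleterious": int(40_000 * scale),
        "LoF": int(10_000 * scale),
    }
    return CohortConfig(
        contigs=[(f"ctg{i}", contig_len) for i in range(1, 5)],
        class_params={
            "synonymous": SelectionClass(0.0, 0.5),
            "tolerated": SelectionClass(0.001, 0.45),
            "deleterious": SelectionClass(0.1, 0.05),
            "LoF": SelectionClass(0.2, 0.05),
        },
        class_budgets=budgets,
        populations=[
            PopulationConfig(
                species="rare",
                n_individuals=32,
                n_populations=9,
                trajectory=DemographicTrajectory([(500, 1), (300, 300)]),
                roh_target_mean=0.2193,
                roh_target_sd=0.05,
                inbreeding=0.2193,
            ),
            PopulationConfig(
                species="widespread",
                n_individuals=51,
                n_populations=17,
                trajectory=DemographicTrajectory([(500, 1), (500, 300)]),
                roh_target_mean=0.1202,
                roh_target_sd=0.04,
                inbreeding=0.1202,
            ),
        ],
    )


@dataclass
class CohortDataset:
    """Sites x individuals genotypes with per-site annotation and truth block.

    genotypes hold ALT dosages: 0/1/2, -1 for missing.  ``sites`` columns:
    contig, pos (1-based), ref, alt, effect_class, population (cohort of
    origin), true_q (terminal derived frequency in that cohort), anc_truth,
    outgroup1, outgroup2.  ``truth`` carries the generating config, seed,
    implanted ROH intervals and achieved F_ROH.
    """

    contigs: pd.DataFrame
    sites: pd.DataFrame
    genotypes: np.ndarray
    individuals: pd.DataFrame
    truth: dict | None = None

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def genome_length(self) -> int:
        return int(self.contigs["length"].sum())

    def subset_sites(self, index) -> "CohortDataset":
        index = np.asarray(index)
        return CohortDataset(
            contigs=self.contigs.copy(),
            sites=self.sites.iloc[index].reset_index(drop=True),
            genotypes=self.genotypes[index],
            individuals=self.individuals.copy(),
            truth=self.truth,
        )

    def validate(self) -> None:
        """Internal-consistency checks; raises AssertionError on breach."""
        assert self.genotypes.shape == (self.n_sites, self.n_individuals), (
            "genotype matrix dimensions inconsistent with sites/individuals"
        )
        assert np.isin(np.unique(self.genotypes), [-1, 0, 1, 2]).all(), (
            "genotypes outside {-1, 0, 1, 2}"
        )
        for contig, grp in self.sites.groupby("contig", sort=False, observed=True):
            pos = grp["pos"].to_numpy()
            assert (np.diff(pos) > 0).all(), f"positions not increasing on {contig}"
        assert self.sites["effect_class"].notna().all(), "unclassified sites"
        if self.truth is not None and "roh_intervals" in self.truth:
            self._check_roh_truth()

    def _check_roh_truth(self) -> None:
        eps = float(self.truth.get("roh_het_error", 0.0))
        intervals = self.truth["roh_intervals"]
        n_het = 0
        n_tot = 0
        ind_index = {v: i for i, v in enumerate(self.individuals["id"])}
        for (ind, contig), grp in intervals.groupby(
            ["individual", "contig"], sort=False, observed=True
        ):
            col = ind_index[ind]
            csites = self.sites[self.sites["contig"] == contig]
            pos = csites["pos"].to_numpy()
            for start, end in grp[["start", "end"]].itertuples(index=False):
                lo, hi = np.searchsorted(pos, [start, end + 1])
                g = self.genotypes[csites.index[lo:hi], col]
                g = g[g >= 0]
                n_het += int((g == 1).sum())
                n_tot += g.size
        if n_tot:
            bound = eps + 4.0 * np.sqrt(max(eps, 1e-12) / n_tot) + 10.0 / n_tot
            assert n_het / n_tot <= bound, (
                f"heterozygote rate inside ROH truth {n_het / n_tot:.2g} exceeds "
                f"error-rate bound {bound:.2g}"
            )


def _draw_positions(rng, contigs, n: int):
    """n distinct 1-based positions across contigs, as (contig_idx, pos), sorted."""
    lengths = np.array([l for _, l in contigs], dtype=np.int64)
    total = lengths.sum()
    if n > total:
        raise ValueError("more sites requested than genome positions")
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    flat = np.array([], dtype=np.int64)
    while flat.size < n:
        extra = rng.integers(0, total, size=int((n - flat.size) * 1.2) + 16)
        flat = np.unique(np.concatenate([flat, extra]))
    flat = np.sort(rng.choice(flat, size=n, replace=False))
    ci = np.searchsorted(offsets, flat, side="right") - 1
    pos = flat - offsets[ci] + 1
    return ci.astype(np.int64), pos.astype(np.int64)


def _mutate_outgroup(rng, anc: np.ndarray, divergence: float, missing_rate: float):
    out = anc.copy()
    if divergence > 0:
        hit = rng.random(anc.size) < divergence
        if hit.any():
            base_idx = np.searchsorted(_BASES, anc[hit])
            shift = rng.integers(1, 4, size=int(hit.sum()))
            out[hit] = _BASES[(base_idx + shift) % 4]
    if missing_rate > 0:
        out[rng.random(anc.size) < missing_rate] = _MISSING
    return out


def generate_cohort(config: CohortConfig, seed: int) -> CohortDataset:
    """Generate a fully specified cohort dataset; deterministic given seed.

    Allele frequencies come from the forward simulator (shared ancestral MSD
    equilibrium, then each cohort's own epochs); genotypes are Hardy-Weinberg
    draws within each cohort; outgroup alleles are Jukes-Cantor substitutions
    of the true ancestral allele; ROH tracts and missingness are applied last.
    """
    if not config.populations:
        raise ValueError("config must name at least one population")
    for name, budget in config.class_budgets.items():
        if name not in config.class_params:
            raise ValueError(f"budget for unknown class {name!r}")
        if budget < 0:
            raise ValueError(f"negative budget for class {name!r}")
    for cname, clen in config.contigs:
        if clen <= 0:
            raise ValueError(f"zero-length contig {cname!r}")

    rng = np.random.default_rng(seed)

    # per-cohort allele frequencies and genotype fragments
    fragments = []  # (pop_index, class_name, q, G)
    for p_idx, pop in enumerate(config.populations):
        class_spec = {
            name: (config.class_params[name], config.class_budgets[name])
            for name in sorted(config.class_budgets)
        }
        sim_seed = int(rng.integers(0, 2**31 - 1))
        frags = simulate_diploid_cohort(
            pop.trajectory, class_spec, pop.n_individuals, sim_seed,
            inbreeding=pop.inbreeding,
        )
        for cname in sorted(frags):
            fragments.append((p_idx, cname, frags[cname]["q"], frags[cname]["genotypes"]))

    n_tot = sum(len(q) for _, _, q, _ in fragments)
    ci, pos = _draw_positions(rng, config.contigs, n_tot)

    # individuals table, cohort by cohort
    ind_rows = []
    col_start = {}
    col = 0
    for p_idx, pop in enumerate(config.populations):
        col_start[p_idx] = col
        for k in range(pop.n_individuals):
            pop_label = f"{pop.species}.p{k % pop.n_populations + 1:02d}"
            ind_rows.append(
                {"id": f"{pop.species}.{k:03d}", "population": pop_label,
                 "species": pop.species}
            )
            col += 1
    individuals = pd.DataFrame(ind_rows)

    # scatter fragments over the sorted site slots
    perm = rng.permutation(n_tot)
    eff_class = np.empty(n_tot, dtype=object)
    pop_of = np.empty(n_tot, dtype=object)
    true_q = np.zeros(n_tot)
    G = np.zeros((n_tot, col), dtype=np.int8)
    cursor = 0
    for p_idx, cname, q, frag_G in fragments:
        rows = perm[cursor : cursor + len(q)]
        cursor += len(q)
        eff_class[rows] = cname
        pop_of[rows] = config.populations[p_idx].species
        true_q[rows] = q
        c0 = col_start[p_idx]
        G[rows, c0 : c0 + frag_G.shape[1]] = frag_G

    ref_idx = rng.integers(0, 4, size=n_tot)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n_tot)) % 4
    ref = _BASES[ref_idx]
    alt = _BASES[alt_idx]
    anc = ref.copy()  # reference genome taken as the ancestral state
    og1 = _mutate_outgroup(rng, anc, config.outgroup_divergence,
                           config.outgroup_missing_rate)
    og2 = _mutate_outgroup(rng, anc, config.outgroup_divergence,
                           config.outgroup_missing_rate)

    contig_names = [c for c, _ in config.contigs]
    sites = pd.DataFrame(
        {
            "contig": pd.Categorical.from_codes(ci, categories=contig_names),
            "pos": pos,
            "ref": ref,
            "alt": alt,
            "effect_class": eff_class,
            "population": pop_of,
            "true_q": true_q,
            "anc_truth": anc,
            "outgroup1": og1,
            "outgroup2": og2,
        }
    )
    contigs = pd.DataFrame(
        {"name": contig_names, "length": [l for _, l in config.contigs]}
    )

    dataset = CohortDataset(
        contigs=contigs,
        sites=sites,
        genotypes=G,
        individuals=individuals,
        truth={
            "seed": seed,
            "config": config.to_dict(),
            "roh_het_error": config.roh_het_error,
        },
    )

    # implanted autozygosity, then missingness
    targets = []
    for p_idx, pop in enumerate(config.populations):
        t = rng.normal(pop.roh_target_mean, pop.roh_target_sd, pop.n_individuals)
        lo = 0.0 if pop.roh_target_mean == 0 else 0.02
        targets.append(np.clip(t, lo, 0.5))
    implant_roh(
        dataset,
        np.concatenate(targets),
        rng=rng,
        min_length=config.roh_min_length,
        mean_extra_length=config.roh_mean_extra_length,
        het_error=config.roh_het_error,
        purging_generations=config.roh_purging_generations,
    )

    if config.missing_rate > 0:
        miss = rng.random(G.shape) < config.missing_rate
        G[miss] = -1

    dataset.validate()
    return dataset


def implant_roh(
    dataset: CohortDataset,
    targets,
    *,
    rng=None,
    seed: int | None = None,
    min_length: int = 100_000,
    mean_extra_length: float = 200_000.0,
    het_error: float = 0.001,
    purging_generations: float = 20.0,
    max_attempts_factor: int = 30,
) -> pd.DataFrame:
    """Implant non-overlapping autozygous tracts until F_ROH targets are met.

    Tract lengths are min_length + Exponential(mean_extra_length); inside a
    tract the genotype is homozygous.  The homozygous allele is drawn from the
    site's cohort frequency weighted by selection over the tract's inbred
    history: P(hom-derived) = q*w / (q*w + 1 - q) with w = (1-s)^g and
    g = ``purging_generations`` — autozygous tracts descend from haplotypes
    whose homozygous state was exposed to selection for about g generations.
    Heterozygotes occur inside tracts at rate ``het_error``.
    Genotypes are modified in place; truth intervals and achieved fractions
    are recorded in ``dataset.truth`` and returned.  Warns (in the truth
    block) when a target cannot be reached on the given contigs.
    """
    targets = np.asarray(targets, dtype=float)
    if targets.size != dataset.n_individuals:
        raise ValueError("one target F_ROH per individual required")
    if np.any((targets < 0) | (targets > 0.9)):
        raise ValueError("target F_ROH must be in [0, 0.9]")
    if rng is None:
        rng = np.random.default_rng(seed)

    genome_len = dataset.genome_length
    contig_names = list(dataset.contigs["name"])
    contig_len = dict(zip(dataset.contigs["name"], dataset.contigs["length"]))
    lengths = np.array([contig_len[c] for c in contig_names], dtype=float)
    contig_w = lengths / lengths.sum()

    # per-contig site lookup
    site_pos = {}
    site_idx = {}
    for cname in contig_names:
        m = dataset.sites["contig"] == cname
        site_pos[cname] = dataset.sites.loc[m, "pos"].to_numpy()
        site_idx[cname] = np.flatnonzero(m.to_numpy())

    # cohort frequency and selection coefficient per site, per species
    class_params = None
    if dataset.truth and "config" in dataset.truth:
        class_params = {
            k: SelectionClass(*v)
            for k, v in dataset.truth["config"]["class_params"].items()
        }
    s_of_site = np.zeros(dataset.n_sites)
    if class_params:
        s_of_site = (
            dataset.sites["effect_class"].map(lambda c: class_params[c].s).to_numpy()
        )
    q_all = dataset.sites["true_q"].to_numpy()
    pop_of_site = dataset.sites["population"].to_numpy()

    records = []
    achieved = np.zeros(targets.size)
    G = dataset.genotypes
    for col, target in enumerate(targets):
        species = dataset.individuals["species"].iloc[col]
        q_ind = np.where(pop_of_site == species, q_all, 0.0)
        occupied: dict[str, list] = {c: [] for c in contig_names}
        covered = 0.0
        attempts = 0
        max_attempts = max_attempts_factor * max(
            1, int(target * genome_len / (min_length + mean_extra_length))
        )
        while covered / genome_len < target and attempts < max_attempts:
            attempts += 1
            length = int(min_length + rng.exponential(mean_extra_length))
            cix = rng.choice(len(contig_names), p=contig_w)
            cname = contig_names[cix]
            if length >= contig_len[cname]:
                continue
            start = int(rng.integers(1, contig_len[cname] - length + 1))
            end = start + length - 1
            if any(s <= end and start <= e for s, e in occupied[cname]):
                continue
            occupied[cname].append((start, end))
            covered += length
            lo, hi = np.searchsorted(site_pos[cname], [start, end + 1])
            rows = site_idx[cname][lo:hi]
            q = q_ind[rows]
            w = (1.0 - s_of_site[rows]) ** purging_generations
            q_eff = q * w / (q * w + (1.0 - q))
            hom = (rng.random(rows.size) < q_eff).astype(np.int8) * 2
            err = rng.random(rows.size) < het_error
            hom[err] = 1
            G[rows, col] = hom
            records.append(
                {
                    "individual": dataset.individuals["id"].iloc[col],
                    "contig": cname,
                    "start": start,
                    "end": end,
                    "length": length,
                }
            )
        achieved[col] = covered / genome_len

    intervals = pd.DataFrame(
        records, columns=["individual", "contig", "start", "end", "length"]
    )
    if dataset.truth is None:
        dataset.truth = {}
    dataset.truth["roh_intervals"] = intervals
    dataset.truth["roh_target"] = targets
    dataset.truth["roh_achieved"] = achieved
    dataset.truth["roh_het_error"] = het_error
    shortfall = targets - achieved
    if np.any(shortfall > 0.01):
        dataset.truth["roh_warning"] = (
            f"{int((shortfall > 0.01).sum())} individuals short of target F_ROH"
        )
    return intervals


# ---------------------------------------------------------------------------
# VCF I/O


def write_vcf(dataset: CohortDataset, path, *, sidecars: bool = True) -> None:
    """Write the dataset as uncompressed VCF 4.2 plus sidecar truth TSVs.

    Effect class, originating cohort, true ancestral allele and outgroup
    alleles are carried in INFO (CLASS, POP, AA, OG1, OG2, TQ) and mirrored in
    ``<path>.classes.tsv`` / ``<path>.outgroups.tsv``; implanted ROH truth (if
    any) goes to ``<path>.roh_truth.bed`` and individuals to
    ``<path>.individuals.tsv``.
    """
    path = str(path)
    gt_map = np.array(["0/0", "0/1", "1/1", "./."])
    s = dataset.sites
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=purgekit-synthetic\n")
        for name, length in dataset.contigs.itertuples(index=False):
            fh.write(f"##contig=<ID={name},length={length}>\n")
        for tag, desc in [
            ("CLASS", "Effect class (synonymous/tolerated/deleterious/LoF)"),
            ("POP", "Cohort in which the variant segregates"),
            ("AA", "True ancestral allele (simulation truth)"),
            ("OG1", "Outgroup 1 allele"),
            ("OG2", "Outgroup 2 allele"),
        ]:
            fh.write(
                f'##INFO=<ID={tag},Number=1,Type=String,Description="{desc}">\n'
            )
        fh.write(
            '##INFO=<ID=TQ,Number=1,Type=Float,Description="True terminal derived '
            'frequency in cohort of origin">\n'
        )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(dataset.individuals["id"])
            + "\n"
        )
        gt_str = gt_map[dataset.genotypes]  # -1 indexes the last entry: "./."
        contig_arr = np.asarray(s["contig"].astype(str))
        for i in range(len(s)):
            info = (
                f"CLASS={s['effect_class'].iat[i]};POP={s['population'].iat[i]};"
                f"AA={s['anc_truth'].iat[i]};OG1={s['outgroup1'].iat[i]};"
                f"OG2={s['outgroup2'].iat[i]};TQ={s['true_q'].iat[i]:.6g}"
            )
            fh.write(
                f"{contig_arr[i]}\t{s['pos'].iat[i]}\t.\t{s['ref'].iat[i]}\t"
                f"{s['alt'].iat[i]}\t.\tPASS\t{info}\tGT\t"
                + "\t".join(gt_str[i])
                + "\n"
            )
    if sidecars:
        s[["contig", "pos", "ref", "alt", "effect_class", "population"]].to_csv(
            path + ".classes.tsv", sep="\t", index=False
        )
        s[["contig", "pos", "anc_truth", "outgroup1", "outgroup2"]].to_csv(
            path + ".outgroups.tsv", sep="\t", index=False
        )
        dataset.individuals.to_csv(path + ".individuals.tsv", sep="\t", index=False)
        if dataset.truth and "roh_intervals" in dataset.truth:
            bed = dataset.truth["roh_intervals"].copy()
            if len(bed):
                # BED is 0-based half-open
                bed["bed_start"] = bed["start"] - 1
                bed[["contig", "bed_start", "end", "individual"]].to_csv(
                    path + ".roh_truth.bed", sep="\t", index=False, header=False
                )


def read_vcf(path, class_table=None, outgroup_table=None, individuals_table=None
             ) -> CohortDataset:
    """Read a biallelic-SNP VCF (as written by :func:`write_vcf`) back.

    Sidecar tables, when given, take precedence over INFO tags.  Non-biallelic
    records raise with the offending position; read-after-write is the
    identity on the data model.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    contigs = pd.DataFrame(
        {"name": list(vcf.seqnames),
         "length": [vcf.seqlens[i] for i in range(len(vcf.seqnames))]}
    )
    rows = []
    gts = []
    # cyvcf2 gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
    gt_code = np.array([0, 1, -1, 2], dtype=np.int8)
    for v in vcf:
        if len(v.ALT) != 1 or v.REF is None or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            raise ValueError(
                f"non-biallelic or non-SNP record at {v.CHROM}:{v.POS}"
            )
        rows.append(
            {
                "contig": v.CHROM,
                "pos": v.POS,
                "ref": v.REF,
                "alt": v.ALT[0],
                "effect_class": v.INFO.get("CLASS"),
                "population": v.INFO.get("POP"),
                "true_q": v.INFO.get("TQ", np.nan),
                "anc_truth": v.INFO.get("AA"),
                "outgroup1": v.INFO.get("OG1"),
                "outgroup2": v.INFO.get("OG2"),
            }
        )
        gts.append(gt_code[v.gt_types])
    sites = pd.DataFrame(rows)
    sites["contig"] = pd.Categorical(sites["contig"], categories=contigs["name"])
    G = np.vstack(gts).astype(np.int8) if gts else np.zeros((0, len(samples)), np.int8)

    if class_table is not None:
        ct = pd.read_csv(class_table, sep="\t")
        sites = sites.drop(columns=["effect_class", "population"]).merge(
            ct, on=["contig", "pos", "ref", "alt"], how="left"
        )
    if outgroup_table is not None:
        ot = pd.read_csv(outgroup_table, sep="\t")
        sites = sites.drop(columns=["anc_truth", "outgroup1", "outgroup2"]).merge(
            ot, on=["contig", "pos"], how="left"
        )
    if individuals_table is not None:
        individuals = pd.read_csv(individuals_table, sep="\t")
    else:
        parts = [sid.rsplit(".", 1) for sid in samples]
        individuals = pd.DataFrame(
            {
                "id": samples,
                "population": [p[0] for p in parts],
                "species": [p[0].split(".")[0] for p in parts],
            }
        )
    return CohortDataset(
        contigs=contigs, sites=sites, genotypes=G, individuals=individuals
    )


# ---------------------------------------------------------------------------
# variant QC

#: GATK-style hard-filter rule: a record fails if ANY clause triggers.
HARD_FILTER_THRESHOLDS = {
    "QUAL": ("<", 30.0),
    "DP": ("<", 5.0),
    "QD": ("<", 2.0),
    "MQ": ("<", 40.0),
    "FS": (">", 60.0),
    "SOR": (">", 3.0),
    "MQRankSum": ("<", -12.5),
    "ReadPosRankSum": ("<", -8.0),
}


def apply_hard_filters(records: pd.DataFrame, thresholds=None):
    """Remove records failing any hard-filter clause; absent annotations pass.

    Returns (surviving records, log) where the log counts removals per clause
    and records per-clause absent-annotation counts.
    """
    if thresholds is None:
        thresholds = HARD_FILTER_THRESHOLDS
    n = len(records)
    fail_any = np.zeros(n, dtype=bool)
    log = {"n_input": n, "clauses": {}}
    for name, (op, cut) in thresholds.items():
        if name in records.columns:
            vals = pd.to_numeric(records[name], errors="coerce")
            absent = int(vals.isna().sum())
            if op == "<":
                fails = (vals < cut).fillna(False).to_numpy()
            elif op == ">":
                fails = (vals > cut).fillna(False).to_numpy()
            else:
                raise ValueError(f"unknown comparison {op!r}")
        else:
            absent = n
            fails = np.zeros(n, dtype=bool)
        log["clauses"][name] = {"failed": int(fails.sum()), "absent": absent}
        fail_any |= fails
    log["n_removed"] = int(fail_any.sum())
    log["n_retained"] = int((~fail_any).sum())
    return records[~fail_any].reset_index(drop=True), log


def site_filters(
    dataset: CohortDataset,
    maf_max_excluded: float = 0.05,
    missing_rate_max: float = 0.10,
):
    """Drop sites with MAF <= maf_max_excluded or missingness >= missing_rate_max.

    Boundary semantics are inclusive on both clauses (a site exactly at either
    threshold is removed), computed across all individuals.  Returns the
    filtered dataset and the kept site indices.
    """
    G = dataset.genotypes
    n_miss = (G == -1).sum(axis=1)
    n_called = G.shape[1] - n_miss
    alt = np.where(G >= 0, G, 0).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        af = np.where(n_called > 0, alt / (2 * n_called), 0.0)
    maf = np.minimum(af, 1.0 - af)
    miss_rate = n_miss / G.shape[1]
    keep = (maf > maf_max_excluded) & (miss_rate < missing_rate_max)
    return dataset.subset_sites(np.flatnonzero(keep)), np.flatnonzero(keep)


def _r2_matrix(G: np.ndarray) -> np.ndarray:
    """Pairwise squared genotype-dosage correlation; missing mean-imputed."""
    X = G.astype(float).T.copy()  # individuals x sites
    miss = X < 0
    X[miss] = np.nan
    mean = np.nanmean(X, axis=0)
    inds = np.where(miss)
    X[inds] = np.take(mean, inds[1])
    X -= X.mean(axis=0)
    denom = np.sqrt((X**2).sum(axis=0))
    denom[denom == 0] = np.nan
    X /= denom
    r = X.T @ X
    return r**2


def ld_prune(
    dataset: CohortDataset,
    window: int = 100,
    step: int = 10,
    r2_max: float = 0.2,
) -> np.ndarray:
    """Greedy windowed LD pruning (PLINK indep-pairphase style).

    Within each ``window``-variant window (slid by ``step``), one of any pair
    of kept sites with r^2 > ``r2_max`` is removed — deterministically the
    later site.  Returns the kept global site indices.
    """
    keep = np.ones(dataset.n_sites, dtype=bool)
    for cname in dataset.contigs["name"]:
        cmask = (dataset.sites["contig"] == cname).to_numpy()
        cidx = np.flatnonzero(cmask)
        m = cidx.size
        if m < 2:
            continue
        for start in range(0, max(1, m - window + 1), step):
            widx = cidx[start : start + window]
            widx = widx[keep[widx]]
            if widx.size < 2:
                continue
            r2 = _r2_matrix(dataset.genotypes[widx])
            local_keep = np.ones(widx.size, dtype=bool)
            for a in range(widx.size):
                if not local_keep[a]:
                    continue
                for b in range(a + 1, widx.size):
                    if local_keep[b] and r2[a, b] > r2_max:
                        local_keep[b] = False
            keep[widx[~local_keep]] = False
    return np.flatnonzero(keep)
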
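"""Empirical genetic-load statistics.

The measurement side of the package: coding-site degeneracy classes,
nucleotide diversity and individual heterozygosity, ROH detection and F_ROH,
outgroup-parsimony polarization, derived-allele counting, the normalized
burden ratios by class / zygosity / ROH stratum, and LD decay.  All functions
accept the :class:`~purgekit.synthetic_data.CohortDataset` container (or plain
arrays where noted) and return tidy pandas tables.

Estimator conventions
---------------------
* pi per variable site is the unbiased pairwise form 2 j (n-j) / (n (n-1))
  over observed (non-missing) alleles; monomorphic positions contribute zero,
  windowed values divide by window length in bp.
* Individual heterozygosity is the per-bp heterozygous-call rate (comparable
  with pi); the inbreeding-style statistic F_het = 1 - obs(het)/exp(het) is
  exposed separately.
* Derived-allele counts are 2 per homozygous-derived genotype plus 1 per
  heterozygote; missing genotypes are excluded from numerators and
  denominators alike.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .synthetic_data import CohortDataset

__all__ = [
    "classify_degeneracy",
    "windowed_pi",
    "individual_heterozygosity",
    "inbreeding_f_het",
    "pi_by_site_class",
    "pi_ratio_0fold_4fold",
    "detect_roh",
    "f_roh",
    "polarize_sites",
    "count_derived",
    "derived_dosage",
    "load_ratios",
    "roh_stratified_ratios",
    "welch_compare",
    "ld_decay",
]

LOAD_CLASSES = ("tolerated", "deleterious", "LoF")
SYNONYMOUS = "synonymous"


# ---------------------------------------------------------------------------
# degeneracy


def _codon_tables():
    from Bio.Data import CodonTable

    fwd = CodonTable.unambiguous_dna_by_id[1].forward_table.copy()
    for stop in CodonTable.unambiguous_dna_by_id[1].stop_codons:
        fwd[stop] = "*"
    return fwd


def classify_degeneracy(genome, gff) -> pd.DataFrame:
    """Fold-degeneracy classes of CDS positions, mapped to genome coordinates.

    For every complete in-frame codon of every transcript, each position is
    classified by the number of the four possible bases that conserve the
    encoded amino acid: 1 -> 0-fold (every change is nonsynonymous), 2 ->
    2-fold, 4 -> 4-fold (every change is synonymous), 3 -> 'other'.
    Strand-aware; transcripts with frame violations or internal stop codons
    are skipped and reported in the ``skipped`` attribute of the result.

    Parameters
    ----------
    genome : dict of str -> str/Seq, or path to a FASTA file
    gff : path to a GFF3 file with CDS features carrying transcript parents

    Returns
    -------
    DataFrame with columns contig, pos (1-based genome), transcript, codon,
    codon_pos (0..2), fold ('0', '2', '4', 'other').
    """
    import gffutils

    if not isinstance(genome, dict):
        from Bio import SeqIO

        genome = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(genome), "fasta")}
    else:
        genome = {k: str(v) for k, v in genome.items()}

    db = gffutils.create_db(
        str(gff), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    aa_of = _codon_tables()
    comp = str.maketrans("ACGT", "TGCA")
    rows = []
    skipped = []

    cds_by_tx: dict[str, list] = {}
    for cds in db.features_of_type("CDS"):
        parents = cds.attributes.get("Parent", [cds.id or "tx"])
        for p in parents:
            cds_by_tx.setdefault(p, []).append(cds)

    for tx, parts in sorted(cds_by_tx.items()):
        parts = sorted(parts, key=lambda c: c.start)
        strand = parts[0].strand
        contig = parts[0].seqid
        seq = "".join(genome[contig][c.start - 1 : c.end] for c in parts)
        coords = np.concatenate(
            [np.arange(c.start, c.end + 1) for c in parts]
        )
        if strand == "-":
            seq = seq.translate(comp)[::-1]
            coords = coords[::-1]
        if len(seq) % 3 != 0:
            skipped.append((tx, "length not divisible by 3"))
            continue
        seq = seq.upper()
        bad = False
        for i in range(0, len(seq) - 3, 3):
            if aa_of.get(seq[i : i + 3]) == "*":
                skipped.append((tx, f"internal stop at codon {i // 3}"))
                bad = True
                break
        if bad:
            continue
        for i in range(0, len(seq), 3):
            codon = seq[i : i + 3]
            if codon not in aa_of:
                continue
            aa = aa_of[codon]
            for off in range(3):
                n_same = sum(
                    aa_of[codon[:off] + b + codon[off + 1 :]] == aa
                    for b in "ACGT"
                )
                fold = {1: "0", 2: "2", 4: "4"}.get(n_same, "other")
                rows.append(
                    (contig, int(coords[i + off]), tx, codon, off, fold)
                )
    out = pd.DataFrame(
        rows, columns=["contig", "pos", "transcript", "codon", "codon_pos", "fold"]
    )
    out.attrs["skipped"] = skipped
    return out


# ---------------------------------------------------------------------------
# diversity


def _site_pi(G: np.ndarray) -> np.ndarray:
    """Unbiased per-site pairwise diversity from a dosage matrix (-1 missing)."""
    called = (G >= 0).sum(axis=1)
    n = 2 * called
    j = np.where(G >= 0, G, 0).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        pi = np.where(n > 1, 2.0 * j * (n - j) / (n * (n - 1.0)), 0.0)
    return pi


def windowed_pi(
    dataset: CohortDataset,
    window: int = 100_000,
    step: int = 10_000,
    by_population: bool = True,
) -> pd.DataFrame:
    """Sliding-window nucleotide diversity per bp (monomorphic bases are zero).

    Windows with no genotyped site are flagged with n_sites = 0 and pi = NA.
    Returns columns population, contig, start, end, n_sites, pi.
    """
    groups = (
        dataset.individuals.groupby("species").groups.items()
        if by_population
        else [("all", dataset.individuals.index)]
    )
    out = []
    for pop, idx in groups:
        G = dataset.genotypes[:, np.asarray(idx)]
        pi_site = _site_pi(G)
        for cname, clen in dataset.contigs.itertuples(index=False):
            cmask = (dataset.sites["contig"] == cname).to_numpy()
            pos = dataset.sites.loc[cmask, "pos"].to_numpy()
            vals = pi_site[cmask]
            cum = np.concatenate([[0.0], np.cumsum(vals)])
            cnt = np.arange(len(pos) + 1)
            starts = np.arange(1, max(clen - window + 2, 2), step)
            lo = np.searchsorted(pos, starts)
            hi = np.searchsorted(pos, starts + window)
            n_sites = cnt[hi] - cnt[lo]
            sums = cum[hi] - cum[lo]
            out.append(
                pd.DataFrame(
                    {
                        "population": pop,
                        "contig": cname,
                        "start": starts,
                        "end": np.minimum(starts + window - 1, clen),
                        "n_sites": n_sites,
                        "pi": np.where(n_sites > 0, sums / window, np.nan),
                    }
                )
            )
    return pd.concat(out, ignore_index=True)


def individual_heterozygosity(
    dataset: CohortDataset, callable_length: int | None = None
) -> pd.Series:
    """Heterozygous calls per bp of callable genome, per individual."""
    L = callable_length if callable_length is not None else dataset.genome_length
    if not L:
        raise ValueError("callable genome length must be positive")
    het = (dataset.genotypes == 1).sum(axis=0)
    return pd.Series(het / L, index=dataset.individuals["id"], name="heterozygosity")


def inbreeding_f_het(dataset: CohortDataset) -> pd.Series:
    """F_het = 1 - observed(het)/expected(het) under HW at sample frequencies."""
    G = dataset.genotypes
    called = (G >= 0).sum(axis=1)
    n = 2 * called
    j = np.where(G >= 0, G, 0).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p_het = np.where(n > 1, 2.0 * j * (n - j) / (n * (n - 1.0)), 0.0)
    obs = (G == 1).sum(axis=0).astype(float)
    exp = np.array(
        [p_het[G[:, k] >= 0].sum() for k in range(G.shape[1])]
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        f = 1.0 - obs / exp
    return pd.Series(f, index=dataset.individuals["id"], name="F_het")


def pi_by_site_class(
    dataset: CohortDataset, site_mask, class_total_sites: int,
    by_population: bool = True,
) -> pd.Series:
    """Per-site pi of a site class, normalized by the class's total site count.

    ``class_total_sites`` is the number of genomic positions of the class
    (monomorphic included); the variable sites selected by ``site_mask``
    contribute the pairwise diversity.
    """
    if class_total_sites <= 0:
        raise ValueError("class_total_sites must be positive")
    site_mask = np.asarray(site_mask)
    groups = (
        dataset.individuals.groupby("species").groups.items()
        if by_population
        else [("all", dataset.individuals.index)]
    )
    out = {}
    for pop, idx in groups:
        G = dataset.genotypes[np.ix_(site_mask.nonzero()[0], np.asarray(idx))]
        out[pop] = _site_pi(G).sum() / class_total_sites
    return pd.Series(out, name="pi")


def pi_ratio_0fold_4fold(dataset: CohortDataset, degmap: pd.DataFrame) -> pd.DataFrame:
    """pi0/pi4 per population from a degeneracy map (see classify_degeneracy).

    Variable sites are intersected with the 0-fold and 4-fold position sets;
    per-site pi is normalized by each class's total position count.  An empty
    4-fold class flags the ratio as NA.
    """
    keys = dataset.sites["contig"].astype(str) + ":" + dataset.sites["pos"].astype(str)
    dkeys = degmap["contig"].astype(str) + ":" + degmap["pos"].astype(str)
    rows = {}
    totals = {}
    for fold in ("0", "4"):
        fold_keys = set(dkeys[degmap["fold"] == fold])
        totals[fold] = len(fold_keys)
        mask = keys.isin(fold_keys).to_numpy()
        if totals[fold] == 0:
            rows[fold] = None
        else:
            rows[fold] = pi_by_site_class(dataset, mask, totals[fold])
    pops = rows["0"].index if rows["0"] is not None else []
    out = []
    for pop in pops:
        pi0 = rows["0"][pop]
        pi4 = rows["4"][pop] if rows["4"] is not None else np.nan
        out.append(
            {
                "population": pop,
                "pi0": pi0,
                "pi4": pi4,
                "ratio": pi0 / pi4 if pi4 and np.isfinite(pi4) and pi4 > 0 else np.nan,
                "n0_sites": totals["0"],
                "n4_sites": totals["4"],
            }
        )
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# runs of homozygosity

LONG_ROH_LENGTH = 1_000_000


def detect_roh(
    dataset: CohortDataset,
    min_length: int = 100_000,
    het_error: float = 1e-3,
    mean_roh_length: float = 500_000.0,
    autozygous_prior: float = 0.15,
) -> pd.DataFrame:
    """Viterbi segmentation of a two-state autozygosity HMM per individual.

    Emissions: P(het | autozygous) = ``het_error``; P(het | non-autozygous) =
    the Hardy-Weinberg heterozygosity 2pq at the individual's population
    allele frequency; missing genotypes are uninformative.  Transition
    probabilities decay with inter-site distance d as 1 - exp(-d/L) with L the
    expected tract (``mean_roh_length``) or gap length (set by
    ``autozygous_prior``).  Segments shorter than ``min_length`` are dropped;
    the > 1 Mb recent-inbreeding class is labelled ``is_long``.

    Sites must be position-sorted within contigs (generator guarantee;
    checked).  Returns columns individual, contig, start, end, length,
    n_sites, is_long.
    """
    eps = max(het_error, 1e-6)
    mean_gap = mean_roh_length * (1.0 - autozygous_prior) / autozygous_prior

    # per-species HW het probability per site
    species = dataset.individuals["species"].to_numpy()
    p_het = np.empty((dataset.n_sites, dataset.n_individuals))
    for sp in np.unique(species):
        cols = np.flatnonzero(species == sp)
        G = dataset.genotypes[:, cols]
        called = (G >= 0).sum(axis=1)
        j = np.where(G >= 0, G, 0).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            q = np.where(called > 0, j / (2 * called), 0.0)
        p = np.clip(2.0 * q * (1.0 - q), 1e-6, 1.0 - 1e-6)
        p_het[:, cols] = p[:, None]

    segments = []
    ids = dataset.individuals["id"].to_numpy()
    for cname in dataset.contigs["name"]:
        cmask = (dataset.sites["contig"] == cname).to_numpy()
        pos = dataset.sites.loc[cmask, "pos"].to_numpy()
        if pos.size == 0:
            continue
        if np.any(np.diff(pos) <= 0):
            raise ValueError(f"sites on {cname} are not position-sorted")
        G = dataset.genotypes[cmask]
        ph = p_het[cmask]
        het = G == 1
        miss = G == -1

        # log emissions, (site, individual, state); state 0 = non-auto, 1 = auto
        ll = np.zeros((pos.size, G.shape[1], 2))
        ll[:, :, 0] = np.where(miss, 0.0, np.where(het, np.log(ph), np.log1p(-ph)))
        ll[:, :, 1] = np.where(
            miss, 0.0, np.where(het, np.log(eps), np.log1p(-eps))
        )

        gaps = np.diff(pos).astype(float)
        p_leave = np.clip(-np.expm1(-gaps / mean_roh_length), 1e-12, 0.5)
        p_enter = np.clip(-np.expm1(-gaps / mean_gap), 1e-12, 0.5)

        n_ind = G.shape[1]
        delta = np.empty((n_ind, 2))
        delta[:, 0] = np.log(1.0 - autozygous_prior) + ll[0, :, 0]
        delta[:, 1] = np.log(autozygous_prior) + ll[0, :, 1]
        psi = np.zeros((pos.size, n_ind, 2), dtype=np.int8)
        for i in range(1, pos.size):
            le, lv = np.log(p_enter[i - 1]), np.log(p_leave[i - 1])
            lse, lsv = np.log1p(-p_enter[i - 1]), np.log1p(-p_leave[i - 1])
            # into state 0: stay from 0, or leave from 1
            stay0 = delta[:, 0] + lse
            from1 = delta[:, 1] + lv
            psi[i, :, 0] = from1 > stay0
            new0 = np.maximum(stay0, from1) + ll[i, :, 0]
            # into state 1: enter from 0, or stay in 1
            from0 = delta[:, 0] + le
            stay1 = delta[:, 1] + lsv
            psi[i, :, 1] = stay1 >= from0
            new1 = np.maximum(from0, stay1) + ll[i, :, 1]
            delta[:, 0] = new0
            delta[:, 1] = new1

        # psi[i, k, s] = 1 iff the best predecessor of state s at site i is 1
        states = np.empty((pos.size, n_ind), dtype=np.int8)
        states[-1] = delta[:, 1] > delta[:, 0]
        ar = np.arange(n_ind)
        for i in range(pos.size - 1, 0, -1):
            cur = states[i]
            states[i - 1] = np.where(cur == 0, psi[i, ar, 0], psi[i, ar, 1])

        for k in range(n_ind):
            st = states[:, k]
            if not st.any():
                continue
            edges = np.flatnonzero(np.diff(np.concatenate([[0], st, [0]])))
            for a, b in zip(edges[::2], edges[1::2]):
                start, end = int(pos[a]), int(pos[b - 1])
                length = end - start + 1
                if length < min_length:
                    continue
                segments.append(
                    {
                        "individual": ids[k],
                        "contig": cname,
                        "start": start,
                        "end": end,
                        "length": length,
                        "n_sites": int(b - a),
                        "is_long": length > LONG_ROH_LENGTH,
                    }
                )
    return pd.DataFrame(
        segments,
        columns=["individual", "contig", "start", "end", "length", "n_sites",
                 "is_long"],
    )


def f_roh(
    segments: pd.DataFrame,
    genome_length: int,
    individuals=None,
    min_length: int = 100_000,
    long_only: bool = False,
) -> pd.Series:
    """Fraction of the genome covered by ROH per individual.

    ``long_only`` restricts to the > 1 Mb recent-inbreeding class.  Overlapping
    segments within an individual violate the segment invariant and raise.
    """
    if genome_length <= 0:
        raise ValueError("genome length must be positive")
    sel = segments[segments["length"] >= min_length]
    if long_only:
        sel = sel[sel["length"] > LONG_ROH_LENGTH]
    for (ind, contig), grp in sel.groupby(["individual", "contig"], observed=True):
        srt = grp.sort_values("start")
        if (srt["start"].to_numpy()[1:] <= srt["end"].to_numpy()[:-1]).any():
            raise ValueError(f"overlapping ROH segments for {ind} on {contig}")
    sums = sel.groupby("individual", observed=True)["length"].sum()
    if individuals is not None:
        sums = sums.reindex(individuals, fill_value=0)
    return (sums / genome_length).rename("f_roh")


# ---------------------------------------------------------------------------
# polarization and derived counts


def polarize_sites(sites: pd.DataFrame, mode: str = "strict") -> pd.DataFrame:
    """Outgroup-parsimony ancestral-state assignment per site.

    strict: the ancestral allele is the allele carried by both outgroups when
    they agree and match REF or ALT; disagreements, double mismatches and
    all-missing outgroups are flagged unpolarized.  relaxed: when only one
    outgroup is informative, its allele is used (flagged single_outgroup).

    Returns a copy of ``sites`` with columns anc_call, derived_is_alt,
    status in {both_agree, single_outgroup, conflict, mismatch, missing}.
    """
    if mode not in ("strict", "relaxed"):
        raise ValueError(f"unknown polarization mode {mode!r}")
    ref = sites["ref"].to_numpy(dtype="<U1")
    alt = sites["alt"].to_numpy(dtype="<U1")
    og1 = sites["outgroup1"].fillna(".").to_numpy(dtype="<U1")
    og2 = sites["outgroup2"].fillna(".").to_numpy(dtype="<U1")
    valid1 = np.isin(og1, list("ACGT"))
    valid2 = np.isin(og2, list("ACGT"))

    anc = np.full(ref.shape, "", dtype="<U1")
    status = np.full(ref.shape, "missing", dtype="<U16")

    both = valid1 & valid2
    agree = both & (og1 == og2)
    conflict = both & (og1 != og2)
    status[conflict] = "conflict"
    match = agree & ((og1 == ref) | (og1 == alt))
    anc[match] = og1[match]
    status[match] = "both_agree"
    status[agree & ~match] = "mismatch"

    if mode == "relaxed":
        one = valid1 ^ valid2
        og = np.where(valid1, og1, og2)
        ok = one & ((og == ref) | (og == alt))
        anc[ok] = og[ok]
        status[ok] = "single_outgroup"
        status[one & ~ok] = "mismatch"

    out = sites.copy()
    out["anc_call"] = anc
    out["status"] = status
    out["polarized"] = anc != ""
    out["derived_is_alt"] = np.where(anc == ref, True, False)
    return out


def count_derived(genotype: int, derived_is_alt: bool = True) -> int:
    """Derived-allele count of one genotype: 2*hom-derived + het; missing excluded.

    ``genotype`` is the ALT dosage (0/1/2, -1 missing).
    """
    if genotype == -1:
        return 0
    if not 0 <= genotype <= 2:
        raise ValueError(f"invalid genotype {genotype}")
    return int(genotype if derived_is_alt else 2 - genotype)


def derived_dosage(G: np.ndarray, derived_is_alt: np.ndarray) -> np.ndarray:
    """Vectorized derived-allele dosage matrix; missing stays -1."""
    D = np.where(derived_is_alt[:, None], G, 2 - G)
    D[G == -1] = -1
    return D.astype(np.int8)


def _class_counts(D: np.ndarray, class_arr, classes) -> dict:
    """Per-individual het/hom derived-site counts for each class."""
    out = {}
    for c in classes:
        m = class_arr == c
        out[c] = {
            "het": (D[m] == 1).sum(axis=0),
            "hom": (D[m] == 2).sum(axis=0),
        }
    return out


def load_ratios(
    dataset: CohortDataset,
    polarization: pd.DataFrame,
    classes=LOAD_CLASSES,
    synonymous: str = SYNONYMOUS,
) -> pd.DataFrame:
    """Zygosity-stratified derived burden ratios per individual.

    For each class c, the het-tract ratio is the number of derived alleles of
    c at heterozygous sites over the same count for synonymous sites (for
    heterozygotes the allele count equals the site count); the hom-tract
    analog uses twice the homozygous-derived site counts.  Unpolarized and
    missing genotypes contribute nothing.  Ratios with a zero synonymous
    denominator are NA.
    """
    mask = polarization["polarized"].to_numpy()
    D = derived_dosage(
        dataset.genotypes[mask], polarization["derived_is_alt"].to_numpy()[mask]
    )
    class_arr = dataset.sites["effect_class"].to_numpy()[mask]
    counts = _class_counts(D, class_arr, list(classes) + [synonymous])
    rows = []
    for k, ind in enumerate(dataset.individuals.itertuples(index=False)):
        den_het = counts[synonymous]["het"][k]
        den_hom = 2 * counts[synonymous]["hom"][k]
        for c in classes:
            het = int(counts[c]["het"][k])
            hom2 = 2 * int(counts[c]["hom"][k])
            rows.append(
                {
                    "individual": ind.id,
                    "species": ind.species,
                    "effect_class": c,
                    "het_count": het,
                    "hom_count": hom2,
                    "syn_het_count": int(den_het),
                    "syn_hom_count": int(den_hom),
                    "het_ratio": het / den_het if den_het else np.nan,
                    "hom_ratio": hom2 / den_hom if den_hom else np.nan,
                }
            )
    return pd.DataFrame(rows)


def _in_roh_mask(dataset: CohortDataset, segments: pd.DataFrame) -> np.ndarray:
    """Boolean (site, individual) matrix: site inside that individual's ROH."""
    mask = np.zeros(dataset.genotypes.shape, dtype=bool)
    col_of = {v: i for i, v in enumerate(dataset.individuals["id"])}
    pos_cache = {
        c: (
            (dataset.sites["contig"] == c).to_numpy(),
            dataset.sites.loc[dataset.sites["contig"] == c, "pos"].to_numpy(),
        )
        for c in dataset.contigs["name"]
    }
    for (ind, contig), grp in segments.groupby(
        ["individual", "contig"], sort=False, observed=True
    ):
        if ind not in col_of or contig not in pos_cache:
            continue
        cmask, pos = pos_cache[contig]
        rows = np.flatnonzero(cmask)
        for start, end in grp[["start", "end"]].itertuples(index=False):
            lo, hi = np.searchsorted(pos, [start, end + 1])
            mask[rows[lo:hi], col_of[ind]] = True
    return mask


def roh_stratified_ratios(
    dataset: CohortDataset,
    segments: pd.DataFrame,
    polarization: pd.DataFrame,
    classes=LOAD_CLASSES,
    synonymous: str = SYNONYMOUS,
) -> pd.DataFrame:
    """Derived burden ratios inside versus outside each individual's ROH.

    Numerators are total derived alleles (2*hom + het) of a class restricted
    to the stratum, normalized by the derived synonymous alleles of the same
    stratum.  Individuals without ROH get NA in-ROH ratios; with no segments
    at all, the outside ratios equal the genome-wide totals.
    """
    pmask = polarization["polarized"].to_numpy()
    D = derived_dosage(
        dataset.genotypes[pmask], polarization["derived_is_alt"].to_numpy()[pmask]
    )
    Dpos = np.where(D > 0, D, 0)
    class_arr = dataset.sites["effect_class"].to_numpy()[pmask]
    in_roh = _in_roh_mask(dataset, segments)[pmask]
    rows = []
    for k, ind in enumerate(dataset.individuals.itertuples(index=False)):
        inr = in_roh[:, k]
        res = {}
        for c in list(classes) + [synonymous]:
            m = class_arr == c
            res[c] = {
                "in": int(Dpos[np.logical_and(m, inr), k].sum()),
                "out": int(Dpos[np.logical_and(m, ~inr), k].sum()),
            }
        den_in = res[synonymous]["in"]
        den_out = res[synonymous]["out"]
        for c in classes:
            rows.append(
                {
                    "individual": ind.id,
                    "species": ind.species,
                    "effect_class": c,
                    "in_count": res[c]["in"],
                    "out_count": res[c]["out"],
                    "syn_in_count": den_in,
                    "syn_out_count": den_out,
                    "in_ratio": res[c]["in"] / den_in if den_in else np.nan,
                    "out_ratio": res[c]["out"] / den_out if den_out else np.nan,
                }
            )
    return pd.DataFrame(rows)


def welch_compare(
    table: pd.DataFrame, value: str, group: str = "species"
) -> pd.DataFrame:
    """Welch's unequal-variance t-test between the two groups, per effect class."""
    rows = []
    if "effect_class" in table.columns:
        groups = table.groupby("effect_class", observed=True)
    else:
        groups = [(None, table)]
    for cls, sub in groups:
        labels = sub[group].unique()
        if len(labels) != 2:
            continue
        a = sub.loc[sub[group] == labels[0], value].dropna()
        b = sub.loc[sub[group] == labels[1], value].dropna()
        t, p = sps.ttest_ind(a, b, equal_var=False)
        rows.append(
            {
                "effect_class": cls,
                "value": value,
                "group_a": labels[0],
                "group_b": labels[1],
                "mean_a": a.mean(),
                "mean_b": b.mean(),
                "t": t,
                "p": p,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# linkage disequilibrium


def ld_decay(
    dataset: CohortDataset,
    max_dist: int = 1_000_000,
    bin_width: int = 10_000,
    max_sites_per_contig: int = 2_000,
    seed: int = 0,
    individuals=None,
) -> pd.DataFrame:
    """Mean genotype-dosage r^2 versus physical distance, in distance bins.

    Intra-contig pairs up to ``max_dist`` apart; contigs denser than
    ``max_sites_per_contig`` are thinned at random (seeded) before the
    all-pairs correlation.  Monomorphic sites are skipped.  The result has
    attrs['half_decay_bp']: the first bin midpoint where mean r^2 falls to
    half its maximum.
    """
    rng = np.random.default_rng(seed)
    cols = (
        np.asarray(individuals)
        if individuals is not None
        else np.arange(dataset.n_individuals)
    )
    sums = np.zeros(max_dist // bin_width + 1)
    cnts = np.zeros_like(sums, dtype=np.int64)
    for cname in dataset.contigs["name"]:
        cmask = (dataset.sites["contig"] == cname).to_numpy()
        pos = dataset.sites.loc[cmask, "pos"].to_numpy()
        G = dataset.genotypes[np.ix_(cmask.nonzero()[0], cols)]
        if pos.size > max_sites_per_contig:
            pick = np.sort(
                rng.choice(pos.size, max_sites_per_contig, replace=False)
            )
            pos, G = pos[pick], G[pick]
        X = G.astype(float)
        X[X < 0] = np.nan
        mean = np.nanmean(X, axis=1, keepdims=True)
        X = np.where(np.isnan(X), mean, X) - mean
        norm = np.sqrt((X**2).sum(axis=1))
        poly = norm > 0
        pos, X, norm = pos[poly], X[poly], norm[poly]
        if pos.size < 2:
            continue
        Xn = X / norm[:, None]
        r2 = (Xn @ Xn.T) ** 2
        d = np.abs(pos[:, None] - pos[None, :])
        iu = np.triu_indices(pos.size, k=1)
        dist = d[iu]
        keep = dist <= max_dist
        b = dist[keep] // bin_width
        np.add.at(sums, b, r2[iu][keep])
        np.add.at(cnts, b, 1)
    mids = np.arange(sums.size) * bin_width + bin_width // 2
    with np.errstate(invalid="ignore"):
        mean_r2 = np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan)
    out = pd.DataFrame({"dist_mid": mids, "mean_r2": mean_r2, "n_pairs": cnts})
    valid = out.dropna(subset=["mean_r2"])
    half = np.nan
    if len(valid):
        peak = valid["mean_r2"].max()
        below = valid[valid["mean_r2"] <= peak / 2]
        if len(below):
            half = float(below["dist_mid"].iloc[0])
    out.attrs["half_decay_bp"] = half
    return out
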
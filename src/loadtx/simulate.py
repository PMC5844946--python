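"""Synthetic-data generators with ground truth for every pipeline input.

Each generator emulates the statistical structure its downstream analysis
assumes and returns a truth record alongside the data, so recovery can be
checked without re-deriving anything from the generator internals:

* mature-miRNA references with "family pairs" at Hamming distance 1 that
  share a long identical block (to exercise ambiguous-assignment handling);
* small-RNA reads built as (end-shifted miRNA)(3' adapter)(padding), with
  optional isomiR 3'-trimming and per-base substitution noise;
* negative-binomial count matrices with a chosen fraction of truly
  differential features at a chosen log2 fold change and per-sample depth
  variation (to exercise upper-quartile normalization);
* beta-binomial editing pileups with group-specific per-site mean levels;
* Ct tables with housekeepers of graded stability and additive group
  effects on target genes.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .editing import EditingSiteTable
from .io import SmallRNARead

BASES = "ACGT"

#: Illumina TruSeq small-RNA 3' adapter, the library chemistry the reads emulate
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(type(o))


def write_truth(truth: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True, default=_json_default)


# ---------------------------------------------------------------------------
# miRNA reference


@dataclass
class ReferenceSim:
    reference: dict[str, str]
    family_pairs: list[tuple[str, str]]


def gen_mirna_reference(
    n_mirnas: int = 50,
    n_family_pairs: int = 3,
    length_range: tuple[int, int] = (20, 23),
    seed: int = 0,
) -> ReferenceSim:
    """Random mature-miRNA reference with engineered near-duplicate pairs.

    Each family pair differs at exactly one position (the last base), so the
    two members share an identical block of length >= 17 by construction and
    a read equal to that block has two tied best hits. Lengths below 18 are
    rejected: a 17-nt exact overlap would not be attainable alongside a
    distinguishing position.
    """
    lo, hi = length_range
    if lo < 18:
        raise ValueError(f"miRNA lengths must be >= 18 nt, got range {length_range}")
    if 2 * n_family_pairs > n_mirnas:
        raise ValueError("more family-pair members than miRNAs")
    if n_mirnas > 4 ** lo / 2:
        raise ValueError("too many distinct sequences for this length range")
    rng = np.random.default_rng(seed)
    reference: dict[str, str] = {}
    seqs: set[str] = set()
    pairs: list[tuple[str, str]] = []

    def draw(length: int) -> str:
        while True:
            s = "".join(rng.choice(list(BASES), size=length))
            if s not in seqs:
                seqs.add(s)
                return s

    idx = 1
    for _ in range(n_family_pairs):
        length = int(rng.integers(lo, hi + 1))
        a = draw(length)
        alt = rng.choice([b for b in BASES if b != a[-1]])
        b = a[:-1] + alt
        if b in seqs:  # vanishingly unlikely; redraw the pair base
            continue
        seqs.add(b)
        na, nb = f"mir-sim-{idx:03d}a", f"mir-sim-{idx:03d}b"
        reference[na], reference[nb] = a, b
        pairs.append((na, nb))
        idx += 1
    while len(reference) < n_mirnas:
        length = int(rng.integers(lo, hi + 1))
        reference[f"mir-sim-{idx:03d}"] = draw(length)
        idx += 1
    return ReferenceSim(reference=reference, family_pairs=pairs)


# ---------------------------------------------------------------------------
# small-RNA reads


@dataclass
class ReadSim:
    reads: list[SmallRNARead]
    truth_counts: dict[str, int]


def gen_small_rna_reads(
    reference: Mapping[str, str],
    abundance: Mapping[str, int],
    adapter: str = DEFAULT_ADAPTER,
    isomir_shift_probs: Sequence[float] = (0.85, 0.10, 0.04, 0.01),
    mismatch_rate: float = 0.0,
    read_length: int = 50,
    seed: int = 0,
) -> ReadSim:
    """Simulate single-end small-RNA reads.

    Each read is (miRNA insert, 3'-trimmed by 0-3 nt with the given
    probabilities)(3' adapter)(random padding), truncated to
    ``read_length``. Substitutions are applied to insert bases at
    ``mismatch_rate`` per base. Truth counts record reads emitted per miRNA.
    """
    if len(adapter) < 8:
        raise ValueError("adapter must be >= 8 nt for the trimmer seed to work")
    if abs(sum(isomir_shift_probs) - 1.0) > 1e-9:
        raise ValueError("isomir_shift_probs must sum to 1")
    unknown = set(abundance) - set(reference)
    if unknown:
        raise ValueError(f"abundance for unknown miRNAs: {sorted(unknown)}")
    if any(v < 0 for v in abundance.values()):
        raise ValueError("abundances must be >= 0")
    rng = np.random.default_rng(seed)
    reads: list[SmallRNARead] = []
    truth: dict[str, int] = {}
    shifts = np.arange(len(isomir_shift_probs))
    i = 0
    for name in sorted(abundance):
        n = int(abundance[name])
        truth[name] = n
        mir = reference[name]
        for _ in range(n):
            shift = int(rng.choice(shifts, p=list(isomir_shift_probs)))
            insert = mir[: max(1, len(mir) - shift)]
            if mismatch_rate > 0:
                bases = list(insert)
                for k in range(len(bases)):
                    if rng.random() < mismatch_rate:
                        bases[k] = rng.choice([b for b in BASES if b != bases[k]])
                insert = "".join(bases)
            seq = insert + adapter
            if len(seq) < read_length:
                seq += "".join(rng.choice(list(BASES), size=read_length - len(seq)))
            seq = seq[:read_length]
            reads.append(SmallRNARead(f"read-{i:06d}", seq, (40,) * len(seq)))
            i += 1
    return ReadSim(reads=reads, truth_counts=truth)


# ---------------------------------------------------------------------------
# count matrices


@dataclass
class CountSim:
    counts: pd.DataFrame
    groups: pd.Series
    true_lfc: dict[str, float]      # DE features only
    base_means: pd.Series
    depth_factors: pd.Series


def gen_count_matrix(
    n_features: int = 2000,
    n_per_group: int = 5,
    de_fraction: float = 0.1,
    lfc: float = 2.0,
    nb_dispersion: float = 0.1,
    mean_range: tuple[float, float] = (20.0, 2000.0),
    depth_sd: float = 0.25,
    seed: int = 0,
) -> CountSim:
    """Negative-binomial feature x sample count matrix with known DE truth.

    Feature base means are log-uniform on ``mean_range``; sample depth
    factors are lognormal with sd ``depth_sd`` (so upper-quartile
    normalization has real work to do); the first ``de_fraction`` of
    features get their case-group means multiplied by 2**lfc (sign
    alternating so both directions occur). Dispersion follows
    var = mu + nb_dispersion * mu**2; a dispersion of 0 degenerates to
    Poisson.
    """
    if not (0.0 <= de_fraction <= 1.0):
        raise ValueError("de_fraction must lie in [0, 1]")
    if n_per_group < 2:
        raise ValueError("need >= 2 samples per group")
    rng = np.random.default_rng(seed)
    features = [f"feat-{i:05d}" for i in range(n_features)]
    samples = [f"ctrl-{j + 1}" for j in range(n_per_group)] + [f"case-{j + 1}" for j in range(n_per_group)]
    groups = pd.Series(["control"] * n_per_group + ["case"] * n_per_group, index=samples, name="group")

    base = np.exp(rng.uniform(np.log(mean_range[0]), np.log(mean_range[1]), size=n_features))
    depth = np.exp(rng.normal(0.0, depth_sd, size=2 * n_per_group))
    n_de = int(round(de_fraction * n_features))
    signs = np.where(np.arange(n_de) % 2 == 0, 1.0, -1.0)
    true_lfc = {features[i]: float(signs[i] * lfc) for i in range(n_de)}

    mu = np.tile(base[:, None], (1, 2 * n_per_group)) * depth[None, :]
    case_cols = np.arange(n_per_group, 2 * n_per_group)
    for i in range(n_de):
        mu[i, case_cols] *= 2.0 ** (signs[i] * lfc)

    if nb_dispersion <= 1e-12:
        counts = rng.poisson(mu)
    else:
        size = 1.0 / nb_dispersion
        p = size / (size + mu)
        counts = rng.negative_binomial(size, p)
    matrix = pd.DataFrame(counts, index=features, columns=samples)
    matrix.index.name = "feature"
    return CountSim(
        counts=matrix, groups=groups, true_lfc=true_lfc,
        base_means=pd.Series(base, index=features),
        depth_factors=pd.Series(depth, index=samples),
    )


# ---------------------------------------------------------------------------
# editing pileups


@dataclass
class EditingSim:
    table: EditingSiteTable
    true_levels: pd.DataFrame     # site x {control, case} mean levels


def gen_editing_pileups(
    sites: pd.DataFrame,
    group_mean_levels: pd.DataFrame,
    concentration: float = 50.0,
    coverage: float = 100.0,
    n_per_group: int = 6,
    dropout: float = 0.0,
    seed: int = 0,
) -> EditingSim:
    """Beta-binomial pileup counts for annotated sites.

    ``sites`` must carry the annotation columns (chrom, pos, strand,
    site_class, gene, aa_change) indexed by site id; ``group_mean_levels``
    has columns 'control' and 'case' with per-site mean editing levels in
    [0, 1]. Per sample, the site's level is Beta(mean * conc, (1 - mean) *
    conc) (degenerate at mean 0 or 1), coverage is Poisson(``coverage``),
    and the edited count is Binomial(coverage, level). ``dropout`` is the
    probability a (site, sample) pileup is missing (total = 0), to exercise
    the coverage filter.
    """
    if concentration <= 0:
        raise ValueError("concentration must be > 0")
    levels = group_mean_levels[["control", "case"]]
    if ((levels < 0) | (levels > 1)).any().any():
        raise ValueError("mean editing levels must lie in [0, 1]")
    if not sites.index.equals(levels.index):
        raise ValueError("sites and group_mean_levels must share an index")
    rng = np.random.default_rng(seed)
    samples = [f"ctrl-{j + 1}" for j in range(n_per_group)] + [f"case-{j + 1}" for j in range(n_per_group)]
    groups = pd.Series(["control"] * n_per_group + ["case"] * n_per_group, index=samples, name="group")

    edited = pd.DataFrame(0, index=sites.index, columns=samples)
    total = pd.DataFrame(0, index=sites.index, columns=samples)
    for s in samples:
        mean = levels["control"] if groups[s] == "control" else levels["case"]
        mean = mean.values
        lv = np.empty_like(mean)
        interior = (mean > 0) & (mean < 1)
        lv[~interior] = mean[~interior]
        lv[interior] = rng.beta(mean[interior] * concentration, (1 - mean[interior]) * concentration)
        cov = rng.poisson(coverage, size=len(mean))
        if dropout > 0:
            cov = np.where(rng.random(len(mean)) < dropout, 0, cov)
        edited[s] = rng.binomial(cov, lv)
        total[s] = cov
    table = EditingSiteTable(sites=sites, edited=edited, total=total, groups=groups)
    return EditingSim(table=table, true_levels=levels.copy())


def default_recoding_sites(n_sites: int = 20, seed: int = 0) -> pd.DataFrame:
    """Synthetic recoding-site annotations (placeholder genes/coordinates)."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_sites):
        chrom = f"chr{int(rng.integers(1, 23))}"
        pos = int(rng.integers(10_000, 200_000_000))
        rows.append({
            "chrom": chrom, "pos": pos, "strand": rng.choice(["+", "-"]),
            "site_class": "recoding", "gene": f"GENE{i + 1}",
            "aa_change": rng.choice(["Q/R", "R/G", "I/V", "Y/C", "K/E"]),
        })
    sites = pd.DataFrame(rows)
    sites.index = pd.Index(sites["chrom"] + ":" + sites["pos"].astype(str), name="site_id")
    return sites


# ---------------------------------------------------------------------------
# Ct tables


@dataclass
class CtSim:
    ct: pd.DataFrame              # long format: sample, group, gene, replicate, ct
    housekeepers: list[str]
    true_log2_effects: dict[str, float]   # expected case-group mean log2_rel per target
    stability_sd: dict[str, float] = field(default_factory=dict)


def gen_ct_table(
    target_effects: Mapping[str, float],
    housekeeper_sd: Mapping[str, float],
    n_per_group: int = 9,
    n_replicates: int = 3,
    base_ct_range: tuple[float, float] = (18.0, 30.0),
    sample_effect_sd: float = 0.5,
    target_sd: float = 0.1,
    replicate_sd: float = 0.1,
    seed: int = 0,
) -> CtSim:
    """Simulate an RT-qPCR Ct table with graded-stability housekeepers.

    Ct(sample, gene, rep) = base_ct(gene) + sample_effect(sample)
    + gene noise (sd = housekeeper_sd[gene] for housekeepers, ``target_sd``
    for targets) - effect (case samples, target genes only) + replicate
    noise. A target's ``target_effects`` value g is its intended case-group
    mean log2 relative expression (-ddCt): up-regulation lowers Ct by g
    cycles. Truth records g per target.
    """
    if len(housekeeper_sd) < 3:
        raise ValueError("need >= 3 candidate housekeepers")
    if n_replicates < 2:
        raise ValueError("need >= 2 technical replicates")
    if n_per_group < 2:
        raise ValueError("need >= 2 samples per group")
    rng = np.random.default_rng(seed)
    samples = [f"ctrl-{j + 1}" for j in range(n_per_group)] + [f"case-{j + 1}" for j in range(n_per_group)]
    group_of = {s: ("control" if s.startswith("ctrl") else "case") for s in samples}
    genes = list(housekeeper_sd) + list(target_effects)
    base_ct = {g: float(rng.uniform(*base_ct_range)) for g in genes}
    sample_effect = {s: float(rng.normal(0.0, sample_effect_sd)) for s in samples}

    rows = []
    for s in samples:
        for g in genes:
            sd = housekeeper_sd.get(g, target_sd)
            gene_noise = float(rng.normal(0.0, sd)) if sd > 0 else 0.0
            shift = target_effects.get(g, 0.0) if group_of[s] == "case" else 0.0
            center = base_ct[g] + sample_effect[s] + gene_noise - shift
            for r in range(1, n_replicates + 1):
                noise = float(rng.normal(0.0, replicate_sd)) if replicate_sd > 0 else 0.0
                rows.append({"sample": s, "group": group_of[s], "gene": g,
                             "replicate": r, "ct": center + noise})
    ct = pd.DataFrame(rows)
    return CtSim(ct=ct, housekeepers=list(housekeeper_sd),
                 true_log2_effects=dict(target_effects),
                 stability_sd=dict(housekeeper_sd))
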
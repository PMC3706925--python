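"""Readers and writers for VCF, counts TSV, breakpoint BED, and manifests.

Positions are 1-based in VCF/TSV and 0-based half-open in BED.  The method
consumes per-site allele counts; producing those from alignments is
upstream of this tool, so counts travel as a plain TSV with columns
chrom, pos, ref, alt, n_ref, n_alt.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .core import PhasedParent, PlasmaCounts, SiteTable, normalize_chrom
from .hmm import FetalCall

logger = logging.getLogger("fetalhap")

COUNTS_COLUMNS = ["chrom", "pos", "ref", "alt", "n_ref", "n_alt"]


# ---------------------------------------------------------------- VCF

def _vcf_header(contigs: list[str], samples: list[str], extra: list[str] = ()) -> str:
    lines = ["##fileformat=VCFv4.2", "##source=fetalhap"]
    lines += [f"##contig=<ID={c}>" for c in contigs]
    lines += list(extra)
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples))
    return "\n".join(lines) + "\n"


def write_phased_vcf(path: str | Path, sites: SiteTable,
                     samples: dict[str, tuple[np.ndarray, np.ndarray]],
                     phased: bool = True,
                     info: dict[str, np.ndarray] | None = None,
                     info_headers: list[str] = ()) -> None:
    """Write one or more samples' haplotypes/genotypes to a VCF.

    ``samples`` maps sample name to a (hap0, hap1) pair of alt-indicator
    arrays; ``hap1 == -1`` writes a haploid call.  ``phased`` selects '|'
    vs '/' separators.
    """
    sep = "|" if phased else "/"
    names = list(samples)
    with open(path, "w") as fh:
        fh.write(_vcf_header(sites.chroms, names, list(info_headers)))
        info = info or {}
        keys = list(info)
        for i in range(len(sites)):
            if keys:
                info_s = ";".join(f"{k}={_fmt_info(info[k][i])}" for k in keys)
            else:
                info_s = "."
            gts = []
            for s in names:
                h0, h1 = samples[s]
                if h1[i] < 0:
                    gts.append(str(int(h0[i])))
                else:
                    gts.append(f"{int(h0[i])}{sep}{int(h1[i])}")
            fh.write(f"{sites.chrom[i]}\t{sites.pos[i]}\t.\t{sites.ref[i]}\t"
                     f"{sites.alt[i]}\t.\tPASS\t{info_s}\tGT\t" + "\t".join(gts) + "\n")


def _fmt_info(v) -> str:
    if isinstance(v, (float, np.floating)):
        return "." if np.isnan(v) else f"{v:.4f}"
    return str(v)


def read_vcf_genotypes(path: str | Path, samples: list[str] | None = None,
                       require_phased: bool = False
                       ) -> tuple[SiteTable, dict[str, tuple[np.ndarray, np.ndarray]]]:
    """Load biallelic SNV genotypes from a VCF via cyvcf2.

    Returns the site table and, per sample, (hap0, hap1) alt-indicator
    arrays (hap1 = -1 for haploid calls).  Multi-allelic, indel, missing
    and (when required) unphased records are dropped with logged counts.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    names = samples if samples is not None else list(vcf.samples)
    missing = [s for s in names if s not in vcf.samples]
    if missing:
        raise ValueError(f"samples {missing} absent from {path}")
    cols = {s: ([], []) for s in names}
    chroms, poss, refs, alts = [], [], [], []
    dropped = {"multiallelic_or_indel": 0, "missing": 0, "unphased": 0, "contig": 0}
    sidx = [vcf.samples.index(s) for s in names]
    for rec in vcf:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            dropped["multiallelic_or_indel"] += 1
            continue
        try:
            chrom = normalize_chrom(rec.CHROM)
        except ValueError:
            dropped["contig"] += 1
            continue
        row = {}
        ok = True
        for s, k in zip(names, sidx):
            g = rec.genotypes[k]  # [a0, a1, phased] or [a0, phased]
            alleles = g[:-1]
            if any(a < 0 for a in alleles):
                dropped["missing"] += 1
                ok = False
                break
            if require_phased and len(alleles) == 2 and not g[-1] \
                    and alleles[0] != alleles[1]:
                dropped["unphased"] += 1
                ok = False
                break
            if len(alleles) == 1:
                row[s] = (alleles[0], -1)
            else:
                row[s] = (alleles[0], alleles[1])
        if not ok:
            continue
        chroms.append(chrom)
        poss.append(rec.POS)
        refs.append(rec.REF)
        alts.append(rec.ALT[0])
        for s in names:
            cols[s][0].append(row[s][0])
            cols[s][1].append(row[s][1])
    for k, v in dropped.items():
        if v:
            logger.info("read_vcf_genotypes(%s): dropped %d records (%s)", path, v, k)
    table = SiteTable(chroms, poss, refs, alts)
    out = {s: (np.asarray(cols[s][0], dtype=np.int8),
               np.asarray(cols[s][1], dtype=np.int8)) for s in names}
    return table, out


def read_phased_parent(path: str | Path, sample: str, role: str) -> PhasedParent:
    sites, gts = read_vcf_genotypes(path, [sample], require_phased=True)
    h0, h1 = gts[sample]
    return PhasedParent(role, sites, h0, h1)


def write_fetal_vcf(path: str | Path, call: FetalCall) -> None:
    """Write the inferred fetal genome; GT order is paternal|maternal and
    INFO carries the decoded state indices and per-parent log-odds."""
    info_headers = [
        '##INFO=<ID=HP,Number=1,Type=Integer,Description="Decoded paternal transmitted haplotype (-1 outside chain)">',
        '##INFO=<ID=HM,Number=1,Type=Integer,Description="Decoded maternal transmitted haplotype (-1 outside chain)">',
        '##INFO=<ID=LODP,Number=1,Type=Float,Description="Natural-log odds paternal hap1 vs hap0">',
        '##INFO=<ID=LODM,Number=1,Type=Float,Description="Natural-log odds maternal hap1 vs hap0">',
        '##fetalhap_GT_order=paternal|maternal',
    ]
    write_phased_vcf(path, call.sites,
                     {"FETUS": (np.where(call.fetal_pat < 0, call.fetal_mat,
                                         call.fetal_pat).astype(np.int8),
                                np.where(call.fetal_pat < 0, -1,
                                         call.fetal_mat).astype(np.int8))},
                     info={"HP": call.hp, "HM": call.hm,
                           "LODP": call.log_odds_pat, "LODM": call.log_odds_mat},
                     info_headers=info_headers)


# ---------------------------------------------------------------- counts TSV

def write_counts_tsv(path: str | Path, counts: PlasmaCounts) -> None:
    counts.to_dataframe().to_csv(path, sep="\t", index=False)


def read_counts_tsv(path: str | Path, sites: SiteTable) -> PlasmaCounts:
    """Load plasma counts and align them to a parental site list.

    Alignment is by (chrom, pos); sites missing from the TSV get zero
    counts (logged), and a ref/alt disagreement at a shared position is a
    hard error (it signals shifted coordinates or a different panel).
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing_cols = [c for c in COUNTS_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"counts TSV missing columns {missing_cols}")
    df["chrom"] = df["chrom"].map(normalize_chrom)
    key = pd.MultiIndex.from_arrays([df["chrom"], df["pos"]])
    lookup = pd.DataFrame(
        {"ref": df["ref"].to_numpy(), "alt": df["alt"].to_numpy(),
         "n_ref": df["n_ref"].to_numpy(), "n_alt": df["n_alt"].to_numpy()},
        index=key)
    want = pd.MultiIndex.from_arrays([sites.chrom, sites.pos])
    joined = lookup.reindex(want)
    found = joined["n_ref"].notna().to_numpy()
    mism = found & ((joined["ref"].to_numpy() != sites.ref)
                    | (joined["alt"].to_numpy() != sites.alt))
    if mism.any():
        i = int(np.flatnonzero(mism)[0])
        raise ValueError(
            f"ref/alt mismatch at {sites.chrom[i]}:{sites.pos[i]} between "
            f"counts TSV and site list")
    n_missing = int((~found).sum())
    if n_missing:
        logger.info("read_counts_tsv(%s): %d sites absent, counts set to 0",
                    path, n_missing)
    n_ref = np.where(found, joined["n_ref"].to_numpy(), 0).astype(np.int64)
    n_alt = np.where(found, joined["n_alt"].to_numpy(), 0).astype(np.int64)
    return PlasmaCounts(sites, n_ref, n_alt)


# ---------------------------------------------------------------- BED

def write_breakpoints_bed(call: FetalCall, path: str | Path) -> None:
    """Breakpoint intervals as BED: 0-based half-open, spanning the two
    flanking informative sites; name column PATERNAL/MATERNAL."""
    with open(path, "w") as fh:
        fh.write("# fetalhap recombination breakpoint intervals\n")
        for parent in ("paternal", "maternal"):
            for c, intervals in call.breakpoints[parent].items():
                for lo, hi in intervals:
                    fh.write(f"{c}\t{lo - 1}\t{hi}\t{parent.upper()}\n")


def read_breakpoints_bed(path: str | Path) -> dict[str, dict[str, list[tuple[int, int]]]]:
    out: dict[str, dict[str, list[tuple[int, int]]]] = {"paternal": {}, "maternal": {}}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            c, s, e, name = line.rstrip("\n").split("\t")[:4]
            out[name.lower()].setdefault(c, []).append((int(s) + 1, int(e)))
    return out


def write_truth_bed(crossovers: dict[str, dict[str, np.ndarray]],
                    path: str | Path) -> None:
    """True crossover points as zero-length-ish BED features (1 bp)."""
    with open(path, "w") as fh:
        fh.write("# fetalhap true crossover positions\n")
        for parent, per_chrom in crossovers.items():
            for c, xs in per_chrom.items():
                for x in np.asarray(xs):
                    p = int(np.floor(x))
                    fh.write(f"{c}\t{p}\t{p + 1}\t{parent.upper()}\n")


# ---------------------------------------------------------------- manifest

def write_manifest(path: str | Path, config: dict) -> None:
    """Serialize a run's parameters (seed always included) as JSON."""
    if "seed" not in config:
        raise ValueError("run manifest must record the seed")
    with open(path, "w") as fh:
        json.dump(config, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, Path):
        return str(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
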
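"""VCF and TSV input/output.

Genotypes travel as VCF (GT field, 1-based positions, one chromosome,
biallelic records only); imputed results carry DS (B-allele dosage, 4
decimals) and GP (genotype probabilities, 6 decimals) per the community
convention for imputation output.  Reading goes through cyvcf2; writing
emits VCF text directly.  Tabular artifacts (panels, marker maps,
per-marker results) are plain TSV read and written with pandas.

On read, dosages are recomputed from the renormalised GP triple so the
dosage/probability identity holds exactly; the DS column itself is the
4-decimal rounding of the written dosages.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .sim import GenotypeMatrix, HaplotypeSet, MarkerMap, MISSING
from .panels import PanelDefinition
from .lshmm import DosageMatrix

__all__ = [
    "write_genotype_vcf",
    "write_haplotype_vcf",
    "write_dosage_vcf",
    "read_genotype_vcf",
    "read_haplotype_vcf",
    "read_dosage_vcf",
    "write_panel_tsv",
    "read_panel_tsv",
    "write_marker_map_tsv",
    "read_marker_map_tsv",
]

_GT_CODE = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def _vcf_header(marker_map: MarkerMap, sample_ids: list[str], fields: list[str]) -> str:
    lines = [
        "##fileformat=VCFv4.2",
        "##source=imputeval",
        f"##contig=<ID={marker_map.chromosome_id}>",
    ]
    if "GT" in fields:
        lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    if "DS" in fields:
        lines.append(
            '##FORMAT=<ID=DS,Number=1,Type=Float,Description="Estimated B-allele dosage">'
        )
    if "GP" in fields:
        lines.append(
            '##FORMAT=<ID=GP,Number=G,Type=Float,Description="Genotype probabilities AA,AB,BB">'
        )
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(sample_ids)
    )
    return "\n".join(lines) + "\n"


def _alleles(marker_map: MarkerMap, l: int) -> tuple[str, str]:
    ref = str(np.asarray(marker_map.ref_alleles, dtype=object)[l])
    alt = str(np.asarray(marker_map.alt_alleles, dtype=object)[l])
    # keep VCF parsers happy when alleles are abstract labels
    if ref not in "ACGTN":
        ref = "A"
    if alt not in "ACGTN" or alt == ref:
        alt = "C" if ref != "C" else "G"
    return ref, alt


def write_genotype_vcf(path, genos: GenotypeMatrix) -> None:
    """Write unphased GT records, one per marker."""
    mm = genos.marker_map
    with open(path, "w") as fh:
        fh.write(_vcf_header(mm, list(genos.individual_ids), ["GT"]))
        for l in range(genos.n_markers):
            ref, alt = _alleles(mm, l)
            cells = "\t".join(_GT_CODE[int(g)] for g in genos.genotypes[:, l])
            fh.write(
                f"{mm.chromosome_id}\t{mm.positions_bp[l]}\tm{l}\t{ref}\t{alt}"
                f"\t.\tPASS\t.\tGT\t{cells}\n"
            )


def write_haplotype_vcf(path, haps: HaplotypeSet) -> None:
    """Write phased GT records; haplotypes are paired 2i | 2i+1."""
    if haps.n_haplotypes % 2:
        raise ValueError("need an even number of haplotypes to write diploids")
    mm = haps.marker_map
    n_dip = haps.n_haplotypes // 2
    ids = [f"ind{i}" for i in range(n_dip)]
    a = haps.alleles
    with open(path, "w") as fh:
        fh.write(_vcf_header(mm, ids, ["GT"]))
        for l in range(haps.n_markers):
            ref, alt = _alleles(mm, l)
            cells = "\t".join(
                f"{a[2 * i, l]}|{a[2 * i + 1, l]}" for i in range(n_dip)
            )
            fh.write(
                f"{mm.chromosome_id}\t{mm.positions_bp[l]}\tm{l}\t{ref}\t{alt}"
                f"\t.\tPASS\t.\tGT\t{cells}\n"
            )


def write_dosage_vcf(path, dosages: DosageMatrix) -> None:
    """Write GT:DS:GP records (GT = most likely genotype)."""
    mm = dosages.marker_map
    p = dosages.genotype_probs
    het = (p[..., 1] >= p[..., 0]) & (p[..., 1] >= p[..., 2])
    calls = np.where(het, 1, np.where(p[..., 0] >= p[..., 2], 0, 2))
    with open(path, "w") as fh:
        fh.write(_vcf_header(mm, list(dosages.individual_ids), ["GT", "DS", "GP"]))
        for l in range(dosages.n_markers):
            ref, alt = _alleles(mm, l)
            cells = "\t".join(
                f"{_GT_CODE[int(calls[i, l])]}:{dosages.dosages[i, l]:.4f}:"
                f"{p[i, l, 0]:.6f},{p[i, l, 1]:.6f},{p[i, l, 2]:.6f}"
                for i in range(dosages.n_individuals)
            )
            fh.write(
                f"{mm.chromosome_id}\t{mm.positions_bp[l]}\tm{l}\t{ref}\t{alt}"
                f"\t.\tPASS\t.\tGT:DS:GP\t{cells}\n"
            )


def _scan(path):
    """Iterate VCF records, rejecting multi-allelic/invalid ones."""
    vcf = VCF(str(path))
    for n, v in enumerate(vcf, start=1):
        if v.ALT is None or len(v.ALT) != 1:
            raise ValueError(
                f"record {n} ({v.CHROM}:{v.POS}): only biallelic records are supported"
            )
        if v.POS is None or v.POS <= 0:
            raise ValueError(f"record {n}: missing or non-positive position")
        yield n, v
    vcf.close()
    return


def _read_core(path):
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    vcf.close()
    chrom = None
    positions, refs, alts, gts = [], [], [], []
    for n, v in _scan(path):
        if chrom is None:
            chrom = v.CHROM
        elif v.CHROM != chrom:
            raise ValueError(f"record {n}: multiple chromosomes in one file")
        positions.append(v.POS)
        refs.append(v.REF)
        alts.append(v.ALT[0])
        gts.append(np.array(v.genotypes, dtype=object))
    if not positions:
        raise ValueError(f"{path}: no records")
    mm = MarkerMap(
        chromosome_id=chrom,
        positions_bp=np.asarray(positions, dtype=np.int64),
        ref_alleles=np.asarray(refs, dtype=object),
        alt_alleles=np.asarray(alts, dtype=object),
    )
    return samples, mm, gts


def read_genotype_vcf(path) -> GenotypeMatrix:
    """Read unphased genotypes (0/1/2, missing for ./.)."""
    samples, mm, gts = _read_core(path)
    n, L = len(samples), len(mm)
    geno = np.full((n, L), MISSING, dtype=np.int8)
    for l, rows in enumerate(gts):
        for i in range(n):
            a, b = int(rows[i][0]), int(rows[i][1])
            if a < 0 or b < 0:
                continue
            geno[i, l] = a + b
    return GenotypeMatrix(genotypes=geno, marker_map=mm, individual_ids=samples)


def read_haplotype_vcf(path) -> HaplotypeSet:
    """Read phased genotypes into a haplotype matrix (rows 2i, 2i+1)."""
    samples, mm, gts = _read_core(path)
    n, L = len(samples), len(mm)
    alleles = np.zeros((2 * n, L), dtype=np.int8)
    for l, rows in enumerate(gts):
        for i in range(n):
            a, b, phased = int(rows[i][0]), int(rows[i][1]), bool(rows[i][2])
            if a < 0 or b < 0 or not phased:
                raise ValueError(
                    f"marker {l}: sample {samples[i]} is unphased or missing; "
                    "reference haplotypes must be fully phased"
                )
            alleles[2 * i, l] = a
            alleles[2 * i + 1, l] = b
    return HaplotypeSet(alleles=alleles, marker_map=mm)


def read_dosage_vcf(path) -> DosageMatrix:
    """Read DS/GP records back into a :class:`DosageMatrix`."""
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    chrom = None
    positions, refs, alts, probs = [], [], [], []
    for n, v in enumerate(vcf, start=1):
        if v.ALT is None or len(v.ALT) != 1:
            raise ValueError(
                f"record {n} ({v.CHROM}:{v.POS}): only biallelic records are supported"
            )
        if chrom is None:
            chrom = v.CHROM
        gp = v.format("GP")
        if gp is None:
            raise ValueError(f"record {n}: GP field is required")
        positions.append(v.POS)
        refs.append(v.REF)
        alts.append(v.ALT[0])
        probs.append(np.asarray(gp, dtype=np.float64))
    vcf.close()
    if not positions:
        raise ValueError(f"{path}: no records")
    mm = MarkerMap(
        chromosome_id=chrom,
        positions_bp=np.asarray(positions, dtype=np.int64),
        ref_alleles=np.asarray(refs, dtype=object),
        alt_alleles=np.asarray(alts, dtype=object),
    )
    p = np.stack(probs, axis=1)  # (N, L, 3)
    p = np.clip(p, 0.0, None)
    p /= p.sum(axis=-1, keepdims=True)
    dosages = p[..., 1] + 2.0 * p[..., 2]
    return DosageMatrix(
        dosages=dosages, genotype_probs=p, marker_map=mm, individual_ids=samples
    )


def write_panel_tsv(path, panel: PanelDefinition) -> None:
    df = pd.DataFrame(
        {
            "chrom": panel.marker_map.chromosome_id,
            "pos_bp": panel.positions_bp,
            "name": panel.name,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_panel_tsv(path, marker_map: MarkerMap) -> PanelDefinition:
    """Read a panel TSV, resolving positions against a marker map."""
    df = pd.read_csv(path, sep="\t")
    for col in ("chrom", "pos_bp", "name"):
        if col not in df.columns:
            raise ValueError(f"panel file missing column {col!r}")
    pos = df["pos_bp"].to_numpy(dtype=np.int64)
    idx = np.searchsorted(marker_map.positions_bp, pos)
    bad = (idx >= len(marker_map)) | (marker_map.positions_bp[np.minimum(idx, len(marker_map) - 1)] != pos)
    if bad.any():
        raise ValueError(
            f"{int(bad.sum())} panel positions are absent from the marker map"
        )
    return PanelDefinition(
        name=str(df["name"].iloc[0]),
        marker_indices=np.sort(idx),
        marker_map=marker_map,
    )


def write_marker_map_tsv(path, marker_map: MarkerMap) -> None:
    df = pd.DataFrame(
        {
            "chrom": marker_map.chromosome_id,
            "pos_bp": marker_map.positions_bp,
            "pos_morgan": marker_map.positions_morgan,
            "ref": np.asarray(marker_map.ref_alleles, dtype=object),
            "alt": np.asarray(marker_map.alt_alleles, dtype=object),
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_marker_map_tsv(path) -> MarkerMap:
    df = pd.read_csv(path, sep="\t")
    pos_bp = df["pos_bp"].to_numpy(dtype=np.int64)
    pos_m = df["pos_morgan"].to_numpy(dtype=float)
    # recover the linear map scale from the data
    scale = pos_m[-1] / pos_bp[-1] if pos_bp[-1] else 0.0
    return MarkerMap(
        chromosome_id=str(df["chrom"].iloc[0]),
        positions_bp=pos_bp,
        morgan_per_bp=scale,
        ref_alleles=df["ref"].to_numpy(dtype=object),
        alt_alleles=df["alt"].to_numpy(dtype=object),
    )
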
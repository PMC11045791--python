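"""Panel variant container and VCF/TSV input-output.

The unit of exchange is :class:`PanelData`: a variant annotation table plus
aligned genotype-dosage and read-depth matrices (variants x samples).  On
disk this is a plain VCF v4.2 with per-variant annotations in INFO
(GENE/GROUP/REGION/CANONICAL/CADD plus QC warning flags) and GT/DP per
sample.  Reading goes through cyvcf2; writing emits text VCF directly
(the schema is small and fixed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["PanelData", "write_vcf", "read_vcf", "write_tsv", "read_tsv"]

VARIANT_COLUMNS = [
    "chrom", "pos", "ref", "alt", "gene", "group", "region", "canonical",
    "cadd", "qual", "filter", "low_complexity", "phase_warning",
    "lowqual_warning",
]

_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1"}


@dataclass
class PanelData:
    """Called panel variants with aligned genotype and depth matrices.

    ``variants`` is indexed by variant_id (``chrom:pos:ref:alt``);
    ``genotypes`` and ``depth`` share that index and have one column per
    sample (genotypes as alt-allele dosage 0/1/2).
    """

    variants: pd.DataFrame
    genotypes: pd.DataFrame
    depth: pd.DataFrame

    def __post_init__(self) -> None:
        if not (
            self.variants.index.equals(self.genotypes.index)
            and self.variants.index.equals(self.depth.index)
        ):
            raise ValueError("variants/genotypes/depth indices differ")
        if list(self.genotypes.columns) != list(self.depth.columns):
            raise ValueError("genotype and depth sample columns differ")

    @property
    def samples(self) -> list[str]:
        return list(self.genotypes.columns)

    @property
    def variant_ids(self) -> pd.Index:
        return self.variants.index

    def subset(self, variant_ids) -> "PanelData":
        idx = pd.Index(variant_ids)
        return PanelData(
            self.variants.loc[idx],
            self.genotypes.loc[idx],
            self.depth.loc[idx],
        )


def _info_string(row: pd.Series) -> str:
    parts = [
        f"GENE={row['gene']}",
        f"GROUP={int(row['group'])}",
        f"REGION={row['region']}",
        f"CANONICAL={int(bool(row['canonical']))}",
    ]
    if pd.notna(row.get("cadd", np.nan)):
        parts.append(f"CADD={row['cadd']:.2f}")
    for col, tag in [
        ("low_complexity", "LOWCPLX"),
        ("phase_warning", "PHASEWARN"),
        ("lowqual_warning", "LOWQUALWARN"),
    ]:
        if bool(row.get(col, False)):
            parts.append(tag)
    return ";".join(parts)


def write_vcf(panel: PanelData, path) -> None:
    """Write the panel as an uncompressed VCF v4.2."""
    samples = panel.samples
    chroms = pd.unique(panel.variants["chrom"].astype(str))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=exogene\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FILTER=<ID=LowQ,Description="Failed caller quality filter">\n')
        fh.write('##INFO=<ID=GENE,Number=1,Type=String,Description="Panel gene symbol">\n')
        fh.write('##INFO=<ID=GROUP,Number=1,Type=Integer,Description="Gene selection group (1-5)">\n')
        fh.write('##INFO=<ID=REGION,Number=1,Type=String,Description="exonic, splice or intronic">\n')
        fh.write('##INFO=<ID=CANONICAL,Number=1,Type=Integer,Description="1 if on canonical transcript">\n')
        fh.write('##INFO=<ID=CADD,Number=1,Type=Float,Description="CADD scaled deleteriousness score">\n')
        fh.write('##INFO=<ID=LOWCPLX,Number=0,Type=Flag,Description="Low-complexity region">\n')
        fh.write('##INFO=<ID=PHASEWARN,Number=0,Type=Flag,Description="In phase with other variants">\n')
        fh.write('##INFO=<ID=LOWQUALWARN,Number=0,Type=Flag,Description="Low-quality call warning">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        gt = panel.genotypes.to_numpy()
        dp = panel.depth.to_numpy()
        for i, (vid, row) in enumerate(panel.variants.iterrows()):
            fields = [
                str(row["chrom"]),
                str(int(row["pos"])),
                str(vid),
                row["ref"],
                row["alt"],
                f"{row['qual']:.1f}",
                row["filter"],
                _info_string(row),
                "GT:DP",
            ]
            calls = [
                f"{_GT_STRINGS[int(g)]}:{int(d)}"
                for g, d in zip(gt[i], dp[i])
            ]
            fh.write("\t".join(fields + calls) + "\n")


def read_vcf(path) -> PanelData:
    """Read a panel VCF (as written by :func:`write_vcf`) via cyvcf2."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, gts, dps, ids = [], [], [], []
    for v in vcf:
        vid = v.ID or f"{v.CHROM}:{v.POS}:{v.REF}:{v.ALT[0]}"
        ids.append(vid)
        rows.append(
            {
                "chrom": v.CHROM,
                "pos": v.POS,
                "ref": v.REF,
                "alt": v.ALT[0],
                "gene": v.INFO.get("GENE"),
                "group": int(v.INFO.get("GROUP")),
                "region": v.INFO.get("REGION"),
                "canonical": bool(int(v.INFO.get("CANONICAL"))),
                "cadd": float(v.INFO.get("CADD"))
                if v.INFO.get("CADD") is not None
                else np.nan,
                "qual": float(v.QUAL),
                "filter": v.FILTER or "PASS",
                "low_complexity": v.INFO.get("LOWCPLX") is not None,
                "phase_warning": v.INFO.get("PHASEWARN") is not None,
                "lowqual_warning": v.INFO.get("LOWQUALWARN") is not None,
            }
        )
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        dosage = np.array(
            [{0: 0, 1: 1, 3: 2}.get(t, 0) for t in v.gt_types], dtype=np.int8
        )
        gts.append(dosage)
        dps.append(np.asarray(v.format("DP")).reshape(-1).astype(int))
    variants = pd.DataFrame(rows, index=pd.Index(ids, name="variant_id"))
    genotypes = pd.DataFrame(np.array(gts), index=variants.index, columns=samples)
    depth = pd.DataFrame(np.array(dps), index=variants.index, columns=samples)
    return PanelData(variants, genotypes, depth)


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    """TSV writer with stable float formatting (byte-identical reruns)."""
    df.to_csv(path, sep="\t", index=index, float_format="%.6g")


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)
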
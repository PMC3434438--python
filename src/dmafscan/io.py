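"""Readers and writers: VCF genotypes, ms-format haplotypes, phenotype TSVs.

Coordinate conventions: VCF positions are 1-based inclusive externally and
converted to the package's 0-based half-open indexing at the boundary;
ms-format positions are fractions of the region length and are scaled to
base pairs on read.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .core import MISSING, GenotypeMatrix, Phenotype, TestResult
from .simulate import RegionPool

logger = logging.getLogger("dmafscan")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def read_vcf(path: str | Path, skip_multiallelic: bool = True) -> GenotypeMatrix:
    """Load diploid GT calls from a VCF into a :class:`GenotypeMatrix`.

    Genotypes become alternate-allele counts 0/1/2 (phase is ignored);
    missing calls become ``-1``.  Multiallelic records are skipped with a
    warning by default; with ``skip_multiallelic=False`` any non-reference
    allele is counted as alternate.
    """
    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"{path}: VCF has no sample columns")
    columns, ids, positions = [], [], []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1:
            if skip_multiallelic:
                n_skipped += 1
                continue
        gt = np.asarray(var.gt_types)  # 0/1/2 alt copies, 3 = unknown
        columns.append(np.where(gt == 3, MISSING, gt).astype(np.int16))
        vid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        ids.append(vid)
        positions.append(var.POS)
    if n_skipped:
        logger.warning("%s: skipped %d multiallelic records", path, n_skipped)
    if not columns:
        raise ValueError(f"{path}: no (biallelic) variants found")
    # duplicate IDs can occur for unnamed records at one position
    seen: dict[str, int] = {}
    for i, vid in enumerate(ids):
        if vid in seen:
            seen[vid] += 1
            ids[i] = f"{vid}_{seen[vid]}"
        else:
            seen[vid] = 0
    return GenotypeMatrix(
        counts=np.column_stack(columns),
        sample_ids=samples,
        variant_ids=ids,
        positions=np.asarray(positions, dtype=np.int64),
    )


_GT_CODE = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(genotypes: GenotypeMatrix, path: str | Path, chrom: str = "region",
              contig_length: int | None = None) -> None:
    """Write a :class:`GenotypeMatrix` as a minimal GT-only VCF."""
    length = contig_length or int(genotypes.positions[-1]) if genotypes.n_variants else 0
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=dmafscan\n")
        fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.sample_ids)
            + "\n"
        )
        for j in range(genotypes.n_variants):
            gts = "\t".join(_GT_CODE[int(c)] for c in genotypes.counts[:, j])
            fh.write(
                f"{chrom}\t{genotypes.positions[j]}\t{genotypes.variant_ids[j]}"
                f"\tA\tC\t.\tPASS\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# ms-format haplotypes
# ---------------------------------------------------------------------------


def read_ms(path: str | Path, length_bp: float) -> list[RegionPool]:
    """Parse ms-format text into one :class:`RegionPool` per replicate block.

    Expects the classical layout per block: a ``//`` separator (optional
    for a single block), ``segsites: k``, ``positions: ...`` (fractions of
    the region, scaled here to base pairs), then one 0/1 row per
    haplotype.  Columns are kept exactly as written (no allele
    re-orientation); ``maf`` is the folded allele-1 frequency.  Pools
    written by :func:`write_ms` from the internal simulator therefore
    round-trip unchanged.
    """
    lines = Path(path).read_text().splitlines()
    blocks: list[list[str]] = []
    current: list[str] | None = None
    for line in lines:
        line = line.strip()
        if line.startswith("//"):
            current = []
            blocks.append(current)
        elif line.startswith("segsites:"):
            if current is None:
                current = []
                blocks.append(current)
            current.append(line)
        elif current is not None and line:
            current.append(line)
    if not blocks:
        raise ValueError(f"{path}: no ms replicate blocks found")

    pools = []
    for bi, block in enumerate(blocks):
        if not block or not block[0].startswith("segsites:"):
            raise ValueError(f"{path}: block {bi} missing 'segsites:' line")
        segsites = int(block[0].split(":")[1])
        if segsites == 0:
            pools.append(
                RegionPool(
                    haplotypes=np.empty((0, 0), dtype=np.int8),
                    positions=np.empty(0),
                    maf=np.empty(0),
                    length_bp=length_bp,
                )
            )
            continue
        if len(block) < 2 or not block[1].startswith("positions:"):
            raise ValueError(f"{path}: block {bi} missing 'positions:' line")
        fracs = np.array([float(x) for x in block[1].split(":")[1].split()])
        if fracs.size != segsites:
            raise ValueError(f"{path}: block {bi} positions count != segsites")
        rows = []
        for row in block[2:]:
            if len(row) != segsites or set(row) - {"0", "1"}:
                raise ValueError(
                    f"{path}: block {bi} haplotype row length/content mismatch"
                )
            rows.append(np.frombuffer(row.encode(), dtype=np.uint8) - ord("0"))
        H = np.array(rows, dtype=np.int8)
        freq = H.mean(axis=0)
        pools.append(
            RegionPool(
                haplotypes=H,
                positions=fracs * length_bp,
                maf=np.minimum(freq, 1.0 - freq),
                length_bp=length_bp,
            )
        )
    return pools


def write_ms(pools: list[RegionPool] | RegionPool, path: str | Path) -> None:
    """Write pool haplotypes as ms-format text (one ``//`` block per pool)."""
    if isinstance(pools, RegionPool):
        pools = [pools]
    with open(path, "w") as fh:
        fh.write("dmafscan ms-format export\n\n")
        for pool in pools:
            fh.write("//\n")
            fh.write(f"segsites: {pool.n_variants}\n")
            fracs = " ".join(
                f"{p / pool.length_bp:.10f}" for p in pool.positions
            )
            fh.write(f"positions: {fracs}\n")
            for row in pool.haplotypes:
                fh.write("".join("1" if x else "0" for x in row) + "\n")


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------


def read_phenotype(path: str | Path, samples: list[str]) -> Phenotype:
    """Read a two-column TSV (``sample_id``, ``status``) aligned to
    ``samples`` (the genotype sample order), matching by id not row order."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if not {"sample_id", "status"} <= set(df.columns):
        raise ValueError(f"{path}: need columns 'sample_id' and 'status'")
    extra = sorted(set(df["sample_id"]) - set(samples))
    if extra:
        raise ValueError(f"{path}: phenotype rows for unknown samples: {extra}")
    missing = sorted(set(samples) - set(df["sample_id"]))
    if missing:
        raise ValueError(f"{path}: no phenotype for samples: {missing}")
    lookup = df.set_index("sample_id")["status"]
    status = lookup.loc[samples].to_numpy()
    if not np.isin(status, (0, 1)).all():
        raise ValueError(f"{path}: status values must be 0 or 1")
    return Phenotype(status=status.astype(np.int8))


def write_phenotype(phenotype: Phenotype, samples: list[str], path: str | Path) -> None:
    pd.DataFrame({"sample_id": samples, "status": phenotype.status}).to_csv(
        path, sep="\t", index=False
    )


def dichotomize_median(values: np.ndarray) -> Phenotype:
    """Median split of a quantitative phenotype into a binary endpoint.

    Values strictly above the median become cases (1); values at or below
    it, including exact ties at the median, become controls (0).  For an
    even number of distinct values this is a 50/50 split.
    """
    v = np.asarray(values, dtype=np.float64)
    if v.ndim != 1 or np.isnan(v).any():
        raise ValueError("values must be a 1-D numeric vector without missing")
    if np.all(v == v[0]):
        raise ValueError("constant phenotype cannot be median-split")
    return Phenotype(status=(v > np.median(v)).astype(np.int8))


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------


def test_result_frame(
    results: list[TestResult], labels: list[str], seed: int | None
) -> pd.DataFrame:
    """Whole-region test results as a TSV-ready table."""
    return pd.DataFrame(
        {
            "variant_set": labels,
            "flavor": [r.flavor for r in results],
            "n_variants": [len(r.variant_set) for r in results],
            "statistic": [r.statistic for r in results],
            "p_value": [r.p_value for r in results],
            "n_perm": [r.n_perm for r in results],
            "seed": seed,
        }
    )


def window_result_frame(scan, genotypes: GenotypeMatrix, size: int,
                        seed: int | None) -> pd.DataFrame:
    """One window size of a scan as a TSV-ready table.

    Variant indices are reported 1-based inclusive; ``start_bp``/``stop_bp``
    are the base-pair positions of the first and last variant per window.
    """
    cols = scan.analysis_variants
    rows = []
    for i, r in enumerate(scan.results[size]):
        first = cols[r.window.start]
        last = cols[r.window.stop - 1]
        rows.append(
            {
                "window_index": i + 1,
                "start_variant": r.window.start + 1,
                "stop_variant": r.window.stop,
                "start_bp": int(genotypes.positions[first]),
                "stop_bp": int(genotypes.positions[last]),
                "statistic": r.statistic,
                "p_raw": r.p_raw,
                "p_corrected": r.p_corrected,
                "seed": seed,
            }
        )
    return pd.DataFrame(rows)
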
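"""Readers and writers for VCF and PLINK PED/MAP text genotypes.

VCF parsing goes through cyvcf2; only the GT field is consumed and only
biallelic SNP records are kept (multiallelic records are skipped with a
warning, or rejected when ``strict_biallelic=True``). The VCF writer emits
the minimal 4.2 subset those readers need and is round-trip tested.

PLINK text conventions: sex 1=male, 2=female, other=unknown; a "0 0"
allele pair is a missing call. The PED format carries no ref/alt
designation, so on reading the alternate allele is taken as the
minor-by-count allele (ties broken toward the lexicographically later
allele); the decision is recorded in the matrix provenance so dosage
polarity is reproducible. An explicit ``alt_alleles`` mapping overrides
the inference.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .genotypes import MISSING, GenotypeError, GenotypeMatrix


class VCFParseError(ValueError):
    """Malformed VCF input."""


class PlinkParseError(ValueError):
    """Malformed PED/MAP input."""


_PED_SEX = {"1": "male", "2": "female"}
_SEX_PED = {"male": "1", "female": "2", "unknown": "0"}


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(
    path: str | Path,
    sex: Mapping[str, str] | None = None,
    strict_biallelic: bool = False,
) -> GenotypeMatrix:
    """Read a VCF into a :class:`GenotypeMatrix`.

    Dosage is the alternate-allele count of the GT call; any call with an
    unknown allele (``./.``) is :data:`MISSING`. ``sex`` optionally maps
    sample id to "male"/"female" (VCFs carry no sex column).
    """
    path = Path(path)
    with open(path, "rt") as fh:
        first = fh.readline()
    if not first.startswith("##fileformat"):
        raise VCFParseError(f"{path}: line 1: missing ##fileformat header line")
    try:
        vcf = VCF(str(path), gts012=False)
    except Exception as exc:  # pragma: no cover - cyvcf2 error paths
        raise VCFParseError(f"{path}: {exc}") from exc

    sample_ids = list(vcf.samples)
    sex = sex or {}
    chroms, poss, ids, refs, alts, rows = [], [], [], [], [], []
    n_multi = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            if strict_biallelic:
                raise VCFParseError(
                    f"{path}: multiallelic record at {rec.CHROM}:{rec.POS}"
                )
            n_multi += 1
            continue
        gts = np.asarray(rec.genotype.array())  # (n_samples, 3): a1, a2, phased
        alleles = gts[:, :2]
        dos = alleles.sum(axis=1).astype(np.int8)
        dos[(alleles < 0).any(axis=1)] = MISSING
        chroms.append(rec.CHROM)
        poss.append(rec.POS)
        ids.append(rec.ID or f"{rec.CHROM}:{rec.POS}")
        refs.append(rec.REF)
        alts.append(rec.ALT[0])
        rows.append(dos)
    vcf.close()
    if n_multi:
        warnings.warn(f"{path}: skipped {n_multi} multiallelic record(s)")

    variants = pd.DataFrame(
        {"chrom": chroms, "pos": poss, "id": ids, "ref": refs, "alt": alts}
    )
    samples = pd.DataFrame(
        {"id": sample_ids, "sex": [sex.get(s, "unknown") for s in sample_ids]},
        dtype=object,
    )
    dosage = (
        np.array(rows, dtype=np.int8).T
        if rows
        else np.zeros((len(sample_ids), 0), dtype=np.int8)
    )
    try:
        return GenotypeMatrix(samples, variants, dosage, {"source": str(path)})
    except GenotypeError as exc:
        raise VCFParseError(f"{path}: {exc}") from exc


_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write a GT-only VCF 4.2 file re-readable by :func:`read_vcf`."""
    path = Path(path)
    with open(path, "wt") as out:
        out.write("##fileformat=VCFv4.2\n")
        out.write("##source=popconserve\n")
        out.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(gm.variants["chrom"]):
            sub = gm.variants.loc[gm.variants["chrom"] == chrom, "pos"]
            out.write(f"##contig=<ID={chrom},length={int(sub.max()) + 1}>\n")
        cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
        out.write("\t".join(cols + gm.sample_ids) + "\n")
        for j, v in enumerate(gm.variants.itertuples()):
            fields = [str(v.chrom), str(v.pos), str(v.id), str(v.ref), str(v.alt),
                      ".", "PASS", ".", "GT"]
            fields.extend(_GT[int(d)] for d in gm.dosage[:, j])
            out.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# PLINK PED/MAP text
# ---------------------------------------------------------------------------

def read_plink_text(
    ped_path: str | Path,
    map_path: str | Path,
    alt_alleles: Mapping[str, str] | None = None,
) -> GenotypeMatrix:
    """Read PLINK whitespace-delimited PED + MAP text files.

    PED columns: FID IID PAT MAT SEX PHENO then two allele columns per
    marker. MAP columns: chrom, marker id, genetic position (cM), bp.
    """
    ped_path, map_path = Path(ped_path), Path(map_path)
    vmap = pd.read_csv(
        map_path,
        sep=r"\s+",
        header=None,
        names=["chrom", "id", "cm", "pos"],
        dtype={"chrom": str, "id": str, "pos": np.int64},
    )
    n_markers = len(vmap)

    ids, sexes, allele_rows = [], [], []
    with open(ped_path, "rt") as fh:
        for lineno, line in enumerate(fh, 1):
            tok = line.split()
            if not tok:
                continue
            if len(tok) != 6 + 2 * n_markers:
                raise PlinkParseError(
                    f"{ped_path}: line {lineno}: expected {6 + 2 * n_markers} fields "
                    f"for {n_markers} markers, got {len(tok)}"
                )
            ids.append(tok[1])
            sexes.append(_PED_SEX.get(tok[4], "unknown"))
            allele_rows.append(tok[6:])
    alleles = np.array(allele_rows, dtype=object).reshape(len(ids), n_markers, 2) \
        if ids else np.empty((0, n_markers, 2), dtype=object)

    dosage = np.full((len(ids), n_markers), MISSING, dtype=np.int8)
    refs, alts = [], []
    inferred = {}
    for j in range(n_markers):
        a = alleles[:, j, :]
        called = (a != "0").all(axis=1) if len(ids) else np.zeros(0, bool)
        obs, counts = np.unique(a[called], return_counts=True)
        marker = vmap["id"].iloc[j]
        if alt_alleles and marker in alt_alleles:
            alt = alt_alleles[marker]
            ref_cands = [x for x in obs if x != alt]
            ref = ref_cands[0] if ref_cands else ("A" if alt != "A" else "C")
        elif len(obs) == 0:
            ref, alt = "N", "A"  # no observed alleles; all calls missing
        elif len(obs) == 1:
            ref, alt = str(obs[0]), "N"  # monomorphic: alt unobservable
        elif len(obs) == 2:
            # minor-by-count is alt; tie -> lexicographically later allele
            if counts[0] == counts[1]:
                ref, alt = sorted(map(str, obs))
            else:
                order = np.argsort(counts)[::-1]
                ref, alt = str(obs[order[0]]), str(obs[order[1]])
            inferred[str(marker)] = alt
        else:
            raise PlinkParseError(
                f"{ped_path}: marker {marker} has >2 alleles: {list(obs)}"
            )
        refs.append(ref)
        alts.append(alt)
        if len(ids):
            dosage[called, j] = (a[called] == alt).sum(axis=1)

    variants = vmap[["chrom", "pos", "id"]].copy()
    variants["ref"] = refs
    variants["alt"] = alts
    samples = pd.DataFrame({"id": ids, "sex": sexes}, dtype=object)
    prov = {"source": str(ped_path), "alt_allele_inference": "minor-by-count"}
    if inferred:
        prov["inferred_alt"] = inferred
    try:
        return GenotypeMatrix(samples, variants, dosage, prov)
    except GenotypeError as exc:
        raise PlinkParseError(f"{ped_path}/{map_path}: {exc}") from exc


def write_plink_text(
    gm: GenotypeMatrix, ped_path: str | Path, map_path: str | Path
) -> None:
    """Write PLINK PED/MAP text re-readable by :func:`read_plink_text`."""
    with open(map_path, "wt") as out:
        for v in gm.variants.itertuples():
            out.write(f"{v.chrom}\t{v.id}\t0\t{v.pos}\n")
    with open(ped_path, "wt") as out:
        for i, s in enumerate(gm.samples.itertuples()):
            fields = [s.id, s.id, "0", "0", _SEX_PED[s.sex], "-9"]
            for j, v in enumerate(gm.variants.itertuples()):
                d = int(gm.dosage[i, j])
                if d == MISSING:
                    fields += ["0", "0"]
                elif d == 0:
                    fields += [v.ref, v.ref]
                elif d == 1:
                    fields += [v.ref, v.alt]
                else:
                    fields += [v.alt, v.alt]
            out.write(" ".join(fields) + "\n")


def write_matrix_tsv(
    df: pd.DataFrame, path: str | Path, header_lines: Sequence[str] = ()
) -> None:
    """Write a DataFrame as TSV with optional ``#``-commented header lines."""
    with open(path, "wt") as out:
        for line in header_lines:
            out.write(f"# {line}\n")
        df.to_csv(out, sep="\t", index=False)
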
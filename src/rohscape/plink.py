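"""PLINK PED/MAP (text) and BED/BIM/FAM (binary, SNP-major v1.00) I/O.

Genotype mapping: 0 = hom A1, 1 = het, 2 = hom A2, -1 = missing.
In the .bed 2-bit code (SNP-major, least-significant bits first):
00 = hom A1, 01 = missing, 10 = het, 11 = hom A2.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, MarkerMap, MISSING

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])
# .bed 2-bit value -> internal code, and back
_BED2CODE = np.array([0, MISSING, 1, 2], dtype=np.int8)
_CODE2BED = {0: 0, MISSING: 1, 1: 2, 2: 3}


class PlinkParseError(ValueError):
    pass


def read_plink(path_prefix: str, format: str = "auto"
               ) -> tuple[GenotypeMatrix, MarkerMap]:
    """Read a PLINK fileset (``prefix.ped``/``.map`` or ``.bed``/``.bim``/``.fam``).

    Markers are returned sorted by (chromosome, position); individual order
    is preserved from the PED/FAM file.
    """
    if format == "auto":
        format = "bed" if os.path.exists(path_prefix + ".bed") else "ped"
    if format == "ped":
        return _read_ped(path_prefix)
    if format == "bed":
        return _read_bed(path_prefix)
    raise ValueError(f"unknown format {format!r}")


def write_plink(G: GenotypeMatrix, M: MarkerMap, path_prefix: str,
                format: str = "ped",
                alleles: pd.DataFrame | None = None) -> None:
    """Write a PLINK fileset.  `alleles` optionally gives per-marker
    (a1, a2) labels; defaults to A/B."""
    if alleles is None:
        alleles = pd.DataFrame({"a1": ["A"] * len(M), "a2": ["B"] * len(M)})
    if format == "ped":
        _write_ped(G, M, path_prefix, alleles)
    elif format == "bed":
        _write_bed(G, M, path_prefix, alleles)
    else:
        raise ValueError(f"unknown format {format!r}")


def _read_map_like(path: str, n_cols: int) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != n_cols:
                raise PlinkParseError(
                    f"{path}:{lineno}: expected {n_cols} fields, got {len(parts)}")
            try:
                int(parts[-1])
            except ValueError:
                raise PlinkParseError(
                    f"{path}:{lineno}: position {parts[-1]!r} is not an integer")
            rows.append(parts)
    return pd.DataFrame(rows)


def _read_ped(prefix: str) -> tuple[GenotypeMatrix, MarkerMap]:
    raw = _read_map_like(prefix + ".map", 4)
    mapframe = pd.DataFrame({"chrom": raw[0].astype(str),
                             "marker_id": raw[1],
                             "pos": raw[3].astype(np.int64)})
    n_markers = len(mapframe)
    ids, allele_rows = [], []
    # A1 is the lexicographically smaller observed allele: a canonical
    # choice that makes write(read(x)) the identity (hom-A1 vs hom-A2 is
    # irrelevant to ROH either way)
    observed: list[set] = [set() for _ in range(n_markers)]
    with open(prefix + ".ped") as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_markers:
                raise PlinkParseError(
                    f"{prefix}.ped:{lineno}: expected {6 + 2 * n_markers} "
                    f"fields, got {len(parts)}")
            ids.append(parts[1])
            pairs = parts[6:]
            for j in range(n_markers):
                x, y = pairs[2 * j], pairs[2 * j + 1]
                if x != "0" and y != "0":
                    observed[j].update((x, y))
                if len(observed[j]) > 2:
                    raise PlinkParseError(
                        f"{prefix}.ped:{lineno}: marker {j} has >2 alleles")
            allele_rows.append(pairs)
    a1 = [min(obs) if obs else "A" for obs in observed]
    geno_rows = []
    for pairs in allele_rows:
        row = np.empty(n_markers, dtype=np.int8)
        for j in range(n_markers):
            x, y = pairs[2 * j], pairs[2 * j + 1]
            if x == "0" or y == "0":
                row[j] = MISSING
            elif x != y:
                row[j] = 1
            else:
                row[j] = 0 if x == a1[j] else 2
        geno_rows.append(row)
    calls = np.vstack(geno_rows) if geno_rows else np.empty((0, n_markers), np.int8)
    return _sort_columns(ids, calls, mapframe)


def _sort_columns(ids: list[str], calls: np.ndarray, mapframe: pd.DataFrame
                  ) -> tuple[GenotypeMatrix, MarkerMap]:
    from .genotypes import _chrom_sort_key

    order = np.asarray(sorted(
        range(len(mapframe)),
        key=lambda i: (_chrom_sort_key(str(mapframe["chrom"].iat[i])),
                       mapframe["pos"].iat[i])))
    M = MarkerMap(mapframe.iloc[order].reset_index(drop=True))
    if calls.shape[0]:
        calls = calls[:, order]
    return GenotypeMatrix(ids, calls), M


def _write_ped(G: GenotypeMatrix, M: MarkerMap, prefix: str,
               alleles: pd.DataFrame) -> None:
    with open(prefix + ".map", "w") as fh:
        for _, r in M.frame.iterrows():
            fh.write(f"{r['chrom']}\t{r['marker_id']}\t0\t{r['pos']}\n")
    a1 = alleles["a1"].to_numpy()
    a2 = alleles["a2"].to_numpy()
    with open(prefix + ".ped", "w") as fh:
        for i, iid in enumerate(G.individual_ids):
            fields = [str(iid), str(iid), "0", "0", "0", "-9"]
            for j, g in enumerate(G.calls[i]):
                if g == MISSING:
                    fields += ["0", "0"]
                elif g == 0:
                    fields += [a1[j], a1[j]]
                elif g == 1:
                    fields += [a1[j], a2[j]]
                else:
                    fields += [a2[j], a2[j]]
            fh.write(" ".join(fields) + "\n")


def _read_bed(prefix: str) -> tuple[GenotypeMatrix, MarkerMap]:
    bim = pd.read_csv(prefix + ".bim", sep=r"\s+", header=None,
                      names=["chrom", "marker_id", "cm", "pos", "a1", "a2"],
                      dtype={"chrom": str})
    if bim["pos"].dtype.kind not in "iu":
        raise PlinkParseError(f"{prefix}.bim: non-integer positions")
    fam = pd.read_csv(prefix + ".fam", sep=r"\s+", header=None,
                      names=["fid", "iid", "pat", "mat", "sex", "pheno"],
                      dtype=str)
    n_ind, n_markers = len(fam), len(bim)
    with open(prefix + ".bed", "rb") as fh:
        magic = fh.read(3)
        if magic != _BED_MAGIC:
            raise PlinkParseError(f"{prefix}.bed: bad magic {magic!r} "
                                  "(need SNP-major v1.00)")
        data = np.frombuffer(fh.read(), dtype=np.uint8)
    bytes_per_snp = (n_ind + 3) // 4
    if len(data) != bytes_per_snp * n_markers:
        raise PlinkParseError(f"{prefix}.bed: size mismatch")
    data = data.reshape(n_markers, bytes_per_snp)
    # unpack 2-bit codes, least-significant pair first
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    twobit = (data[:, :, None] >> shifts) & 0b11          # (snp, byte, 4)
    twobit = twobit.reshape(n_markers, bytes_per_snp * 4)[:, :n_ind]
    calls = _BED2CODE[twobit].T                            # individuals x markers
    return _sort_columns(list(fam["iid"]), calls,
                         bim[["chrom", "marker_id", "pos"]].copy())


def _write_bed(G: GenotypeMatrix, M: MarkerMap, prefix: str,
               alleles: pd.DataFrame) -> None:
    with open(prefix + ".bim", "w") as fh:
        for j, (_, r) in enumerate(M.frame.iterrows()):
            fh.write(f"{r['chrom']}\t{r['marker_id']}\t0\t{r['pos']}\t"
                     f"{alleles['a1'].iat[j]}\t{alleles['a2'].iat[j]}\n")
    with open(prefix + ".fam", "w") as fh:
        for iid in G.individual_ids:
            fh.write(f"{iid} {iid} 0 0 0 -9\n")
    n_ind, n_markers = G.n_individuals, G.n_markers
    bytes_per_snp = (n_ind + 3) // 4
    with open(prefix + ".bed", "wb") as fh:
        fh.write(_BED_MAGIC)
        codes = G.calls.T.astype(np.int8)                  # (snp, ind)
        twobit = np.empty_like(codes, dtype=np.uint8)
        twobit[codes == 0] = 0
        twobit[codes == MISSING] = 1
        twobit[codes == 1] = 2
        twobit[codes == 2] = 3
        padded = np.zeros((n_markers, bytes_per_snp * 4), dtype=np.uint8)
        padded[:, :n_ind] = twobit
        padded = padded.reshape(n_markers, bytes_per_snp, 4)
        shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
        packed = (padded << shifts).sum(axis=2).astype(np.uint8)
        fh.write(packed.tobytes())
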
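"""Reading and writing of genotype matrices, genetic maps, metadata and trees.

The primary on-disk genotype format is a delimited samples-in-rows matrix
with a two-line header: line one carries the locus identifiers, line two the
allele pair observed at each locus (e.g. ``A/G``).  Calls are coded
``AA``/``AB``/``BB`` (``A`` = first allele of the pair as encountered in the
source data, never re-polarised to the minor allele) and missing values as
``NA``.  HapMap diploid tables and biallelic VCF are accepted as convenience
dialects.  In memory a genotype is an allele-B dose in {0, 1, 2} with ``-1``
marking missing.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

logger = logging.getLogger("wheatpopgen")

#: sentinel for a missing genotype in dose encoding
MISSING: int = -1

#: accepted missing-value tokens on read; the first is written
MISSING_TOKENS = ("NA", "--", "./.", "NN", "N")

#: the 21 chromosomes of hexaploid bread wheat
WHEAT_CHROMOSOMES = tuple(f"{n}{g}" for n in range(1, 8) for g in "ABD")

_CALL_TO_DOSE = {"AA": 0, "AB": 1, "BA": 1, "BB": 2}
_DOSE_TO_CALL = {0: "AA", 1: "AB", 2: "BB", MISSING: "NA"}


class ParseError(ValueError):
    """A file could not be parsed in the requested dialect."""


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """A samples x loci biallelic SNP panel in allele-dose encoding.

    Parameters
    ----------
    sample_ids, locus_ids
        Ordered, unique identifiers.
    doses
        ``(n_samples, n_loci)`` int8 array with values in {0, 1, 2, -1}.
    era_labels
        Optional per-sample class label (e.g. ``landrace`` / ``modern``).
    alleles
        Optional per-locus allele pair as read from the source file.
    """

    sample_ids: list[str]
    locus_ids: list[str]
    doses: np.ndarray
    era_labels: np.ndarray | None = None
    alleles: list[tuple[str, str]] | None = None

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=np.int8)
        if len(self.sample_ids) != len(set(self.sample_ids)):
            raise ValueError("sample_ids must be unique")
        if len(self.locus_ids) != len(set(self.locus_ids)):
            raise ValueError("locus_ids must be unique")
        if self.doses.shape != (len(self.sample_ids), len(self.locus_ids)):
            raise ValueError(
                f"doses shape {self.doses.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.locus_ids)} loci"
            )
        if len(self.sample_ids) < 2 or len(self.locus_ids) < 1:
            raise ValueError("need at least 2 samples and 1 locus")
        bad = ~np.isin(self.doses, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError(f"{bad.sum()} dose values outside {{0,1,2,{MISSING}}}")
        if self.era_labels is not None:
            self.era_labels = np.asarray(self.era_labels, dtype=object)
            if self.era_labels.shape[0] != len(self.sample_ids):
                raise ValueError("era_labels length mismatch")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    def locus_index(self, locus_ids) -> np.ndarray:
        lookup = {l: i for i, l in enumerate(self.locus_ids)}
        return np.array([lookup[l] for l in locus_ids], dtype=int)

    def subset_loci(self, keep) -> "GenotypeMatrix":
        """Return a new matrix restricted to loci *keep* (ids or boolean mask)."""
        keep = np.asarray(keep)
        idx = np.flatnonzero(keep) if keep.dtype == bool else self.locus_index(keep)
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            locus_ids=[self.locus_ids[i] for i in idx],
            doses=self.doses[:, idx].copy(),
            era_labels=None if self.era_labels is None else self.era_labels.copy(),
            alleles=None if self.alleles is None else [self.alleles[i] for i in idx],
        )

    def subset_samples(self, keep) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            lookup = {s: i for i, s in enumerate(self.sample_ids)}
            idx = np.array([lookup[s] for s in keep], dtype=int)
        return GenotypeMatrix(
            sample_ids=[self.sample_ids[i] for i in idx],
            locus_ids=list(self.locus_ids),
            doses=self.doses[idx, :].copy(),
            era_labels=None if self.era_labels is None else self.era_labels[idx].copy(),
            alleles=None if self.alleles is None else list(self.alleles),
        )


@dataclass
class GeneticMap:
    """Marker coordinates: chromosome (1A..7D), genome (A/B/D) and cM position.

    Markers are kept sorted within chromosome by position, ties broken by
    locus id, so downstream scans are deterministic.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        req = {"locus_id", "chromosome", "position_cM"}
        if not req.issubset(self.table.columns):
            raise ValueError(f"map table needs columns {sorted(req)}")
        t = self.table.copy()
        bad = sorted(set(t["chromosome"]) - set(WHEAT_CHROMOSOMES))
        if bad:
            raise ValueError(f"unknown chromosome labels: {bad}")
        if t["locus_id"].duplicated().any():
            dups = t.loc[t["locus_id"].duplicated(), "locus_id"].tolist()
            raise ValueError(f"duplicate loci in map: {dups[:5]}")
        pos = t["position_cM"].to_numpy(float)
        if not np.all(np.isfinite(pos)) or (pos < 0).any():
            raise ValueError("positions must be finite and >= 0")
        t["genome"] = t["chromosome"].str[-1]
        t = t.sort_values(["chromosome", "position_cM", "locus_id"], kind="mergesort")
        self.table = t.reset_index(drop=True)

    @property
    def locus_ids(self) -> list[str]:
        return self.table["locus_id"].tolist()

    def positions(self) -> dict[str, float]:
        return dict(zip(self.table["locus_id"], self.table["position_cM"]))

    def chromosome_of(self) -> dict[str, str]:
        return dict(zip(self.table["locus_id"], self.table["chromosome"]))

    def loci_on(self, chromosome: str) -> pd.DataFrame:
        return self.table[self.table["chromosome"] == chromosome]

    def chromosomes(self) -> list[str]:
        return sorted(self.table["chromosome"].unique())


@dataclass
class SampleMetadata:
    """Accession metadata: era class, country and Mediterranean region."""

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if "sample_id" not in self.table.columns or "era" not in self.table.columns:
            raise ValueError("metadata needs at least sample_id and era columns")
        if self.table["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_id in metadata")

    def era_for(self, sample_ids) -> np.ndarray:
        lookup = dict(zip(self.table["sample_id"], self.table["era"]))
        missing = [s for s in sample_ids if s not in lookup]
        if missing:
            raise ValueError(f"samples absent from metadata: {missing[:5]}")
        return np.array([lookup[s] for s in sample_ids], dtype=object)


# ---------------------------------------------------------------------------
# genotype matrix dialects
# ---------------------------------------------------------------------------

def read_genotype_matrix(path, dialect: str = "matrix") -> GenotypeMatrix:
    """Read a genotype file into dose encoding.

    ``dialect`` is one of ``matrix`` (native two-header-line table),
    ``hapmap`` or ``vcf``.  Multi-allelic records are rejected per locus; if
    more than half the records are rejected the file itself is refused.
    """
    readers = {"matrix": _read_matrix, "hapmap": _read_hapmap, "vcf": _read_vcf}
    if dialect not in readers:
        raise ValueError(f"unknown dialect {dialect!r}; choose from {sorted(readers)}")
    return readers[dialect](Path(path))


def _decode_call(token: str, line_no: int) -> int:
    if token in MISSING_TOKENS:
        return MISSING
    try:
        return _CALL_TO_DOSE[token]
    except KeyError:
        raise ParseError(f"line {line_no}: unrecognised call {token!r}") from None


def _read_matrix(path: Path) -> GenotypeMatrix:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if len(lines) < 4:
        raise ParseError(f"{path}: matrix dialect needs 2 header lines and >=2 samples")
    sep = "\t" if "\t" in lines[0] else ","
    head = lines[0].split(sep)
    allele_row = lines[1].split(sep)
    if head[0].lower() not in {"sample", "sample_id", "id"}:
        raise ParseError(f"line 1: first header field is {head[0]!r}, expected 'sample'")
    if allele_row[0].lower() != "alleles":
        raise ParseError(f"line 2: first field is {allele_row[0]!r}, expected 'alleles'")
    locus_ids = head[1:]
    if len(allele_row) != len(head):
        raise ParseError("line 2: allele row length does not match locus header")
    alleles = []
    for tok in allele_row[1:]:
        pair = tok.split("/")
        if len(pair) != 2:
            raise ParseError(f"line 2: bad allele pair {tok!r}")
        alleles.append((pair[0], pair[1]))
    sample_ids, rows = [], []
    for ln_no, ln in enumerate(lines[2:], start=3):
        fields = ln.split(sep)
        if len(fields) != len(head):
            raise ParseError(f"line {ln_no}: expected {len(head)} fields, got {len(fields)}")
        sample_ids.append(fields[0])
        rows.append([_decode_call(tok, ln_no) for tok in fields[1:]])
    return GenotypeMatrix(sample_ids, locus_ids, np.array(rows, dtype=np.int8),
                          alleles=alleles)


def write_genotype_matrix(gm: GenotypeMatrix, path) -> None:
    """Write the native matrix dialect (tab-separated, ``NA`` for missing)."""
    alleles = gm.alleles or [("A", "B")] * gm.n_loci
    with open(path, "w") as fh:
        fh.write("sample\t" + "\t".join(gm.locus_ids) + "\n")
        fh.write("alleles\t" + "\t".join(f"{a}/{b}" for a, b in alleles) + "\n")
        for i, sid in enumerate(gm.sample_ids):
            calls = [_DOSE_TO_CALL[int(d)] for d in gm.doses[i]]
            fh.write(sid + "\t" + "\t".join(calls) + "\n")


_HAPMAP_FIXED = 11  # rs#, alleles, chrom, pos, strand, assembly#, center,
                    # protLSID, assayLSID, panelLSID, QCcode


def _read_hapmap(path: Path) -> GenotypeMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) <= _HAPMAP_FIXED or not header[0].startswith("rs"):
            raise ParseError(f"{path}: line 1: not a HapMap header")
        sample_ids = header[_HAPMAP_FIXED:]
        locus_ids, alleles, rows = [], [], []
        n_rejected = 0
        for ln_no, ln in enumerate(fh, start=2):
            f = ln.rstrip("\n").split("\t")
            if len(f) != len(header):
                raise ParseError(f"line {ln_no}: field count mismatch")
            pair = f[1].split("/")
            if len(pair) != 2:
                n_rejected += 1
                continue
            a, b = pair
            dose_of = {a + a: 0, a + b: 1, b + a: 1, b + b: 2}
            row, ok = [], True
            for tok in f[_HAPMAP_FIXED:]:
                if tok in MISSING_TOKENS:
                    row.append(MISSING)
                elif tok in dose_of:
                    row.append(dose_of[tok])
                else:
                    ok = False  # a third allele appears in the calls
                    break
            if not ok:
                n_rejected += 1
                continue
            locus_ids.append(f[0])
            alleles.append((a, b))
            rows.append(row)
    _check_rejections(path, n_rejected, n_rejected + len(locus_ids))
    return GenotypeMatrix(sample_ids, locus_ids,
                          np.array(rows, dtype=np.int8).T.copy(), alleles=alleles)


def _read_vcf(path: Path) -> GenotypeMatrix:
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading VCF requires cyvcf2") from exc
    vcf = VCF(str(path), gts012=True)
    sample_ids = list(vcf.samples)
    locus_ids, alleles, cols = [], [], []
    n_rejected = 0
    for rec in vcf:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            n_rejected += 1
            continue
        # gt_types: 0=hom ref, 1=het, 2=hom alt (gts012), 3=missing
        g = rec.gt_types.astype(np.int8)
        g[g == 3] = MISSING
        locus_ids.append(rec.ID or f"{rec.CHROM}_{rec.POS}")
        alleles.append((rec.REF, rec.ALT[0]))
        cols.append(g)
    _check_rejections(path, n_rejected, n_rejected + len(locus_ids))
    return GenotypeMatrix(sample_ids, locus_ids,
                          np.array(cols, dtype=np.int8).T.copy(), alleles=alleles)


def _check_rejections(path: Path, n_rejected: int, n_total: int) -> None:
    if n_rejected:
        logger.warning("%s: rejected %d non-biallelic records", path, n_rejected)
    if n_total == 0:
        raise ParseError(f"{path}: no genotype records")
    if n_rejected > 0.5 * n_total:
        raise ParseError(
            f"{path}: {n_rejected}/{n_total} records rejected as non-biallelic"
        )


# ---------------------------------------------------------------------------
# genetic map and metadata
# ---------------------------------------------------------------------------

def read_genetic_map(path, genotypes: GenotypeMatrix | None = None) -> GeneticMap:
    """Read a delimited genetic map with columns locus_id, chromosome, cM.

    If *genotypes* is given, map loci absent from the panel are flagged in
    the log (they are kept; the panel drives which loci are analysed).
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype={0: str})
    cols = {c.lower(): c for c in df.columns}
    ren = {}
    for want, aliases in {
        "locus_id": ("locus_id", "locus", "marker", "rs#", "snp"),
        "chromosome": ("chromosome", "chrom", "chr"),
        "position_cM": ("position_cm", "cm", "position", "pos_cm"),
    }.items():
        for a in aliases:
            if a in cols:
                ren[cols[a]] = want
                break
        else:
            raise ParseError(f"{path}: missing a column for {want}")
    gmap = GeneticMap(df.rename(columns=ren)[["locus_id", "chromosome", "position_cM"]])
    if genotypes is not None:
        extra = set(gmap.locus_ids) - set(genotypes.locus_ids)
        if extra:
            logger.info("%s: %d map loci absent from genotype panel", path, len(extra))
    return gmap


def write_genetic_map(gmap: GeneticMap, path) -> None:
    gmap.table[["locus_id", "chromosome", "genome", "position_cM"]].to_csv(
        path, sep="\t", index=False
    )


def read_sample_metadata(path) -> SampleMetadata:
    return SampleMetadata(pd.read_csv(path, sep=None, engine="python", dtype=str))


def write_sample_metadata(meta: SampleMetadata, path) -> None:
    meta.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

def write_newick(tree: TreeNode, path) -> None:
    """Write an unrooted tree (trifurcating root convention) as Newick.

    Branch lengths are formatted with 10 significant digits.
    """
    s = _newick_string(tree)
    with open(path, "w") as fh:
        fh.write(s + "\n")


def read_newick(path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")


def _newick_string(node: TreeNode) -> str:
    def fmt(n: TreeNode) -> str:
        if n.is_tip():
            body = _quote_label(n.name or "")
        else:
            body = "(" + ",".join(fmt(c) for c in n.children) + ")"
            if n.name:
                body += _quote_label(n.name)
        if n.length is not None:
            body += f":{n.length:.10g}"
        return body

    return fmt(node) + ";"


def _quote_label(label: str) -> str:
    if re.search(r"[\s()\[\]:;,']", label):
        return "'" + label.replace("'", "''") + "'"
    return label
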
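"""Readers, writers and phenotype-preparation filters.

Every external format the pipeline touches is plain text: pedigree and
phenotype tables as CSV, genotypes as PLINK ``.raw``-style allele counts with
a separate marker map, and gene annotation as GFF3 or BED.  Coordinates are
normalized to 1-based inclusive on read regardless of source dialect.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: sentinel for a missing parent; "0" and "" in files both map here
UNKNOWN = "0"

MALE = "M"
FEMALE = "F"

_SEX_ALIASES = {
    "m": MALE, "male": MALE, "1": MALE,
    "f": FEMALE, "female": FEMALE, "2": FEMALE,
}


class PedigreeError(ValueError):
    """Raised for structural pedigree defects (cycles, sex conflicts)."""


def normalize_chromosome(label: object, x_aliases: Iterable[str] = ("X", "30")) -> str:
    """Strip any ``chr`` prefix, uppercase, and map X aliases to ``"X"``.

    Bovine files use both ``X`` and ``30`` for the X chromosome; both are
    accepted by default.
    """
    s = str(label).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    s = s.upper()
    if s in {str(a).upper() for a in x_aliases}:
        return "X"
    return s


# ---------------------------------------------------------------------------
# Pedigree
# ---------------------------------------------------------------------------

@dataclass
class Pedigree:
    """Topologically ordered pedigree (parents always precede offspring).

    Attributes
    ----------
    ids, sire, dam : arrays of str
        ``UNKNOWN`` marks a missing parent.
    sex : array of str
        ``"M"`` or ``"F"``.
    """

    ids: np.ndarray
    sire: np.ndarray
    dam: np.ndarray
    sex: np.ndarray

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.sire = np.asarray(self.sire, dtype=object)
        self.dam = np.asarray(self.dam, dtype=object)
        self.sex = np.asarray(self.sex, dtype=object)
        if len(set(self.ids)) != len(self.ids):
            dupes = pd.Series(self.ids).value_counts()
            raise PedigreeError(
                f"duplicate ids: {list(dupes[dupes > 1].index)[:5]}")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def index(self) -> dict:
        """id -> topological position."""
        return {i: k for k, i in enumerate(self.ids)}

    def parent_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """Sire/dam positions in topological order, -1 when unknown."""
        idx = self.index
        s = np.array([idx.get(p, -1) for p in self.sire], dtype=np.int64)
        d = np.array([idx.get(p, -1) for p in self.dam], dtype=np.int64)
        return s, d

    def is_founder(self) -> np.ndarray:
        return np.array([s == UNKNOWN and d == UNKNOWN
                         for s, d in zip(self.sire, self.dam)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"id": self.ids, "sire": self.sire,
                             "dam": self.dam, "sex": self.sex})

    @classmethod
    def from_records(cls, records: Sequence[tuple]) -> "Pedigree":
        """Build from (id, sire, dam, sex) tuples; reorders topologically."""
        df = pd.DataFrame(records, columns=["id", "sire", "dam", "sex"])
        return _pedigree_from_frame(df)


def _norm_parent(x: object) -> str:
    s = "" if x is None else str(x).strip()
    if s in ("", "0", "NA", "nan", ".", "-"):
        return UNKNOWN
    return s


def _norm_sex(x: object) -> str:
    s = "" if x is None else str(x).strip().lower()
    return _SEX_ALIASES.get(s, "")


def _pedigree_from_frame(df: pd.DataFrame) -> Pedigree:
    ids = [str(i).strip() for i in df["id"]]
    sire = [_norm_parent(s) for s in df["sire"]]
    dam = [_norm_parent(d) for d in df["dam"]]
    sex = [_norm_sex(s) for s in df.get("sex", [""] * len(ids))]

    sires_used = {s for s in sire if s != UNKNOWN}
    dams_used = {d for d in dam if d != UNKNOWN}
    conflict = sires_used & dams_used
    if conflict:
        raise PedigreeError(
            f"animals used as both sire and dam: {sorted(conflict)[:5]}")

    known = set(ids)
    rows = list(zip(ids, sire, dam, sex))
    # implicit parents (appear only as sire/dam) become founders
    for p in sorted((sires_used | dams_used) - known):
        rows.append((p, UNKNOWN, UNKNOWN, ""))

    by_id = {}
    for rid, s, d, x in rows:
        if x == "":
            x = MALE if rid in sires_used else (FEMALE if rid in dams_used else "")
        if rid in sires_used and x != MALE:
            raise PedigreeError(f"{rid} is a sire but recorded as {x or 'unknown'}")
        if rid in dams_used and x != FEMALE:
            raise PedigreeError(f"{rid} is a dam but recorded as {x or 'unknown'}")
        by_id[rid] = (s, d, x or MALE)  # unlinked unsexed animals default male

    order = _topological_order(by_id)
    ids_o = np.array(order, dtype=object)
    return Pedigree(
        ids=ids_o,
        sire=np.array([by_id[i][0] for i in order], dtype=object),
        dam=np.array([by_id[i][1] for i in order], dtype=object),
        sex=np.array([by_id[i][2] for i in order], dtype=object),
    )


def _topological_order(by_id: Mapping[str, tuple]) -> list[str]:
    """Kahn's algorithm, stable in input order; raises naming a cycle."""
    indeg = {i: 0 for i in by_id}
    children: dict[str, list[str]] = {i: [] for i in by_id}
    for cid, (s, d, _) in by_id.items():
        for p in (s, d):
            if p != UNKNOWN:
                indeg[cid] += 1
                children[p].append(cid)
    queue = [i for i in by_id if indeg[i] == 0]
    out: list[str] = []
    while queue:
        nxt = queue.pop(0)
        out.append(nxt)
        for c in children[nxt]:
            indeg[c] -= 1
            if indeg[c] == 0:
                queue.append(c)
    if len(out) != len(by_id):
        cycle = sorted(i for i in by_id if i not in set(out))
        raise PedigreeError(f"pedigree cycle involving: {cycle}")
    return out


def read_pedigree(path: str | Path) -> Pedigree:
    """Read a CSV/TSV pedigree with header ``id,sire,dam,sex``.

    Missing parents may be coded ``0`` or empty.  Sexes of unlabelled parents
    are inferred from their role.  The result is topologically ordered.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str,
                     keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"id", "sire", "dam"}
    if not required <= set(df.columns):
        raise ValueError(f"pedigree file needs columns {sorted(required)}")
    return _pedigree_from_frame(df)


def write_pedigree(ped: Pedigree, path: str | Path) -> None:
    ped.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

@dataclass
class TraitMeta:
    name: str
    response_type: str = "continuous"  # continuous | ordinal | binary
    n_categories: int | None = None


@dataclass
class PhenotypeTable:
    """Per-animal records for one trait plus its model columns.

    ``data`` must carry an ``id`` column, the trait column, and whatever
    fixed-effect / covariate / random-group columns the model references
    (e.g. CG, CRI, DTJN, IDAP, GMAND).
    """

    data: pd.DataFrame
    trait: TraitMeta

    def __post_init__(self) -> None:
        if "id" not in self.data.columns:
            raise ValueError("phenotype table needs an 'id' column")
        if self.trait.name not in self.data.columns:
            raise ValueError(f"trait column {self.trait.name!r} missing")
        if self.data["id"].duplicated().any():
            raise ValueError("an animal appears more than once for this trait")
        if self.trait.response_type in ("ordinal", "binary"):
            vals = self.data[self.trait.name].dropna()
            k = self.trait.n_categories or int(vals.max())
            ok = vals.isin(range(1, k + 1))
            if not ok.all():
                raise ValueError(f"ordinal values outside 1..{k}")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def y(self) -> np.ndarray:
        return self.data[self.trait.name].to_numpy(dtype=float)


def read_phenotypes(path: str | Path, trait: TraitMeta) -> PhenotypeTable:
    df = pd.read_csv(path)
    df["id"] = df["id"].astype(str)
    return PhenotypeTable(df, trait)


def filter_contemporary_groups(
    pheno: PhenotypeTable,
    ped: Pedigree,
    min_size: int = 5,
    min_sires: int = 2,
    cg_col: str = "CG",
) -> tuple[PhenotypeTable, dict]:
    """Apply the contemporary-group preparation filters.

    Removes rows whose CG has fewer than ``min_size`` animals, whose CG's
    members descend from fewer than ``min_sires`` distinct *known* sires, or
    whose animal has both parents unknown.  Returns the filtered table and a
    removal report with counts per rule (each removed row is attributed to
    the first rule that fails, in the order: unknown pedigree, CG size,
    CG sire count).
    """
    df = pheno.data.copy()
    sire_of = dict(zip(ped.ids, ped.sire))
    dam_of = dict(zip(ped.ids, ped.dam))

    unknown_ped = df["id"].map(
        lambda i: sire_of.get(i, UNKNOWN) == UNKNOWN
        and dam_of.get(i, UNKNOWN) == UNKNOWN)

    report = {"unknown_pedigree": int(unknown_ped.sum()),
              "cg_size": 0, "cg_sires": 0}
    kept = df[~unknown_ped]

    sizes = kept.groupby(cg_col)["id"].size()
    small = set(sizes[sizes < min_size].index)
    in_small = kept[cg_col].isin(small)
    report["cg_size"] = int(in_small.sum())
    kept = kept[~in_small]

    def n_known_sires(ids: pd.Series) -> int:
        return len({sire_of.get(i, UNKNOWN) for i in ids} - {UNKNOWN})

    nsires = kept.groupby(cg_col)["id"].agg(n_known_sires)
    few = set(nsires[nsires < min_sires].index)
    in_few = kept[cg_col].isin(few)
    report["cg_sires"] = int(in_few.sum())
    kept = kept[~in_few]

    if kept.empty:
        logger.warning("contemporary-group filtering removed every record")
    report["before"] = len(df)
    report["after"] = len(kept)
    return PhenotypeTable(kept.reset_index(drop=True), pheno.trait), report


# ---------------------------------------------------------------------------
# Gene annotation
# ---------------------------------------------------------------------------

@dataclass
class GeneSet:
    """Gene intervals with 1-based inclusive coordinates."""

    data: pd.DataFrame  # columns: id, name, chrom, start, end, strand, biotype

    def __post_init__(self) -> None:
        bad = self.data["start"] > self.data["end"]
        if bad.any():
            raise ValueError("gene with start > end")

    def __len__(self) -> int:
        return len(self.data)


_GFF_ATTR = re.compile(r"(\w+)[=\s]\"?([^\";]+)\"?")


def _gff_attrs(s: str) -> dict:
    return {k: v.strip() for k, v in _GFF_ATTR.findall(s)}


def read_gene_annotation(path: str | Path) -> GeneSet:
    """Read genes from GFF3 (``type == gene``) or BED6(+biotype).

    BED half-open 0-based intervals are converted to 1-based inclusive so the
    two dialects produce identical entries for the same gene.  Records with
    unparseable coordinates are skipped and counted.
    """
    path = Path(path)
    is_gff = path.suffix.lower() in (".gff", ".gff3") or _sniff_gff(path)
    rows, skipped = [], 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            try:
                if is_gff:
                    if len(f) < 9 or f[2] != "gene":
                        continue
                    attrs = _gff_attrs(f[8])
                    rows.append({
                        "id": attrs.get("ID", attrs.get("gene_id", f"{f[0]}:{f[3]}")),
                        "name": attrs.get("Name", attrs.get("gene_name", "")),
                        "chrom": normalize_chromosome(f[0]),
                        "start": int(f[3]), "end": int(f[4]),
                        "strand": f[6],
                        "biotype": attrs.get("biotype", attrs.get("gene_biotype", "")),
                    })
                else:
                    if len(f) < 4:
                        raise ValueError("short BED line")
                    rows.append({
                        "id": f[3], "name": f[3],
                        "chrom": normalize_chromosome(f[0]),
                        "start": int(f[1]) + 1, "end": int(f[2]),
                        "strand": f[5] if len(f) > 5 else ".",
                        "biotype": f[6] if len(f) > 6 else "",
                    })
            except (ValueError, IndexError):
                skipped += 1
    if skipped:
        logger.warning("skipped %d unparseable annotation records", skipped)
    if not rows:
        logger.warning("no gene records found in %s", path)
        return GeneSet(pd.DataFrame(
            columns=["id", "name", "chrom", "start", "end", "strand", "biotype"]))
    return GeneSet(pd.DataFrame(rows))


def _sniff_gff(path: Path) -> bool:
    with open(path) as fh:
        for line in fh:
            if line.startswith("##gff"):
                return True
            if line.startswith("#"):
                continue
            return len(line.split("\t")) >= 9
    return False


# ---------------------------------------------------------------------------
# Genotypes (container lives in genotype_qc; this is the file-format side)
# ---------------------------------------------------------------------------

def read_marker_map(path: str | Path) -> pd.DataFrame:
    """Read ``snp, chrom, pos, A, B`` TSV; adds a normalized ``is_x`` flag."""
    m = pd.read_csv(path, sep=None, engine="python", dtype=str)
    m.columns = [c.strip().lower() for c in m.columns]
    cols = {"snp", "chrom", "pos"}
    if not cols <= set(m.columns):
        raise ValueError(f"marker map needs columns {sorted(cols)}")
    if m["snp"].duplicated().any():
        dupes = m.loc[m["snp"].duplicated(), "snp"].tolist()
        raise ValueError(f"duplicated SNP ids in map: {dupes[:5]}")
    m["chrom"] = m["chrom"].map(normalize_chromosome)
    m["pos"] = pd.to_numeric(m["pos"], errors="coerce")
    m["is_x"] = m["chrom"] == "X"
    for c in ("a", "b"):
        if c not in m.columns:
            m[c] = ""
    return m


def read_genotypes(geno_path: str | Path, map_path: str | Path,
                   pedigree: Pedigree | None = None):
    """Read a PLINK ``.raw``-style allele-count file joined with a marker map.

    Returns a raw-coded :class:`~xherit.genotype_qc.GenotypeSet`.  Sex per
    animal comes from the file's SEX column when present, overridden by the
    pedigree when given.  X markers are carried and flagged, not dropped.
    """
    from .genotype_qc import GenotypeSet  # deferred: avoids import cycle

    mmap = read_marker_map(map_path)
    df = pd.read_csv(geno_path, sep=r"\s+", dtype=str, keep_default_na=False)
    meta_cols = [c for c in ("FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE")
                 if c in df.columns]
    if "IID" not in df.columns:
        raise ValueError("genotype file needs an IID column")
    snp_cols = [c for c in df.columns if c not in meta_cols]
    # .raw appends the counted allele as SNP_A; strip it for the map join
    snp_names = [c.rsplit("_", 1)[0] if "_" in c else c for c in snp_cols]
    missing = [s for s in snp_names if s not in set(mmap["snp"])]
    if missing:
        raise ValueError(f"SNPs absent from map: {missing[:5]}")
    mmap = mmap.set_index("snp").loc[snp_names].reset_index()

    calls = (df[snp_cols].apply(pd.to_numeric, errors="coerce")
             .to_numpy(dtype=float))
    ids = df["IID"].to_numpy(dtype=object)

    sex = np.array([""] * len(ids), dtype=object)
    if "SEX" in df.columns:
        sex = np.array([_norm_sex(s) for s in df["SEX"]], dtype=object)
    if pedigree is not None:
        sex_of = dict(zip(pedigree.ids, pedigree.sex))
        ped_sex = np.array([sex_of.get(i, "") for i in ids], dtype=object)
        sex = np.where(ped_sex != "", ped_sex, sex)
    if (sex == "").any():
        missing_sex = ids[sex == ""]
        raise ValueError(f"no sex available for animals: {list(missing_sex)[:5]}")

    return GenotypeSet(
        ids=ids, sex=sex,
        snp=mmap["snp"].to_numpy(dtype=object),
        chrom=mmap["chrom"].to_numpy(dtype=object),
        pos=mmap["pos"].to_numpy(dtype=float),
        allele_a=mmap["a"].to_numpy(dtype=object),
        allele_b=mmap["b"].to_numpy(dtype=object),
        is_x=mmap["is_x"].to_numpy(dtype=bool),
        calls=calls, coding="raw",
    )


def write_genotypes(g, geno_path: str | Path, map_path: str | Path) -> None:
    """Re-emit a GenotypeSet in the same ``.raw`` + map text formats."""
    mm = pd.DataFrame({"snp": g.snp, "chrom": g.chrom,
                       "pos": g.pos.astype(int), "a": g.allele_a,
                       "b": g.allele_b})
    mm.to_csv(map_path, sep="\t", index=False)
    cols = {"FID": g.ids, "IID": g.ids,
            "PAT": "0", "MAT": "0",
            "SEX": np.where(g.sex == MALE, 1, 2), "PHENOTYPE": -9}
    df = pd.DataFrame(cols)
    calls = pd.DataFrame(g.calls, columns=[f"{s}_{b}" for s, b in
                                           zip(g.snp, g.allele_b)])
    out = pd.concat([df.reset_index(drop=True), calls], axis=1)
    with open(geno_path, "w") as fh:
        fh.write(" ".join(out.columns) + "\n")
        for _, row in out.iterrows():
            vals = [("NA" if isinstance(v, float) and np.isnan(v)
                     else str(int(v)) if isinstance(v, float) else str(v))
                    for v in row]
            fh.write(" ".join(vals) + "\n")
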
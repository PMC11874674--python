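"""Genotype tables, clutch bookkeeping, and mtDNA haplotype collapsing.

Diploid multilocus genotypes are stored as canonical unordered allele pairs
(integer fragment sizes in bp, low allele first; ``0`` encodes a missing call,
following the GenePop convention).  Aligned mitochondrial control-region
sequences are collapsed to haplotypes after removing every alignment column
that contains a gap, ``N`` or IUPAC ambiguity in any sequence, so a single
informative alignment length applies to all samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

MISSING = 0

ROLE_EMBRYO = "embryo"
ROLE_ADULT = "adult"

_UNAMBIGUOUS = frozenset("ACGT")


class GenotypeFileError(ValueError):
    """Raised for malformed genotype input files."""


@dataclass(frozen=True)
class MarkerDef:
    """A microsatellite locus: name, repeat motif and observed allele sizes."""

    name: str
    repeat_motif: str | None = None
    allele_set: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("locus name must be non-empty")
        if self.allele_set:
            if any(b <= a for a, b in zip(self.allele_set, self.allele_set[1:])):
                raise ValueError(f"{self.name}: allele_set must be strictly increasing")


@dataclass(frozen=True)
class Clutch:
    """Embryos co-hosted by one brooding host female."""

    clutch_id: str
    embryo_ids: tuple[str, ...]
    host_species: str | None = None

    def __post_init__(self) -> None:
        if len(self.embryo_ids) < 1:
            raise ValueError(f"clutch {self.clutch_id} has no embryos")

    @property
    def size(self) -> int:
        return len(self.embryo_ids)


@dataclass
class GenotypeTable:
    """Individuals (embryos and adults) x loci with unordered diploid calls.

    ``meta`` is indexed by sample id with columns ``clutch_id``, ``year`` and
    ``role``; ``calls[locus]`` is an ``(n, 2)`` integer array aligned with
    ``meta`` rows, each row sorted ascending, ``(0, 0)`` meaning missing.
    """

    meta: pd.DataFrame
    calls: dict[str, np.ndarray]
    loci: list[str]

    def __post_init__(self) -> None:
        if self.meta.index.has_duplicates:
            dupes = self.meta.index[self.meta.index.duplicated()].tolist()
            raise GenotypeFileError(f"duplicate sample ids: {dupes}")
        n = len(self.meta)
        for locus in self.loci:
            arr = np.asarray(self.calls[locus], dtype=int)
            if arr.shape != (n, 2):
                raise ValueError(f"{locus}: calls shape {arr.shape} != ({n}, 2)")
            half = (arr == MISSING).sum(axis=1) == 1
            if half.any():
                sample = self.meta.index[half.argmax()]
                raise GenotypeFileError(
                    f"sample {sample}, locus {locus}: one allele of a pair is missing"
                )
            self.calls[locus] = np.sort(arr, axis=1)

    # -- accessors ---------------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.meta)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.meta.index)

    def row(self, sample_id: str) -> int:
        return int(self.meta.index.get_loc(sample_id))

    def call(self, sample_id: str, locus: str) -> tuple[int, int] | None:
        a, b = self.calls[locus][self.row(sample_id)]
        if a == MISSING:
            return None
        return int(a), int(b)

    def sample_calls(self, sample_id: str) -> dict[str, tuple[int, int] | None]:
        return {locus: self.call(sample_id, locus) for locus in self.loci}

    def subset(self, sample_ids) -> "GenotypeTable":
        sample_ids = list(sample_ids)
        rows = [self.row(s) for s in sample_ids]
        return GenotypeTable(
            meta=self.meta.iloc[rows].copy(),
            calls={loc: self.calls[loc][rows].copy() for loc in self.loci},
            loci=list(self.loci),
        )

    def ids_with_role(self, role: str) -> list[str]:
        return list(self.meta.index[self.meta["role"] == role])

    @property
    def embryo_ids(self) -> list[str]:
        return self.ids_with_role(ROLE_EMBRYO)

    @property
    def adult_ids(self) -> list[str]:
        return self.ids_with_role(ROLE_ADULT)

    def allele_universe(self, locus: str) -> list[int]:
        arr = self.calls[locus]
        return sorted(int(a) for a in np.unique(arr) if a != MISSING)

    # -- I/O ---------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        out = self.meta.reset_index().rename(columns={"index": "sample_id"})
        if "sample_id" not in out.columns:
            out = out.rename(columns={out.columns[0]: "sample_id"})
        for locus in self.loci:
            out[f"{locus}_1"] = self.calls[locus][:, 0]
            out[f"{locus}_2"] = self.calls[locus][:, 1]
        return out

    def write_csv(self, path) -> None:
        frame = self.to_frame()
        for locus in self.loci:
            for col in (f"{locus}_1", f"{locus}_2"):
                frame[col] = frame[col].replace(MISSING, pd.NA)
        frame.to_csv(path, index=False, na_rep="NA")

    def write_genepop(self, path, title: str = "clutchkin export") -> None:
        """Four-digit GenePop export (one population, missing = 0000)."""
        lines = [title]
        lines.extend(self.loci)
        lines.append("Pop")
        for sid in self.sample_ids:
            parts = []
            for locus in self.loci:
                a, b = self.calls[locus][self.row(sid)]
                parts.append(f"{a:04d}{b:04d}")
            lines.append(f"{sid} , " + " ".join(parts))
        Path(path).write_text("\n".join(lines) + "\n")


def _canonical_pair(a, b, sample: str, locus: str) -> tuple[int, int]:
    if (a == MISSING) != (b == MISSING):
        raise GenotypeFileError(
            f"sample {sample}, locus {locus}: odd allele count in call ({a}, {b})"
        )
    return (min(a, b), max(a, b))


def read_genotype_table(path, panel_spec=None, dialect: str = "wide") -> GenotypeTable:
    """Read a genotype CSV.

    ``wide`` dialect expects two columns ``<locus>_1``/``<locus>_2`` per locus;
    ``slash`` expects a single ``<locus>`` column holding ``a/b``.  Missing
    calls may be written ``NA``, empty, or ``0``.  ``panel_spec`` (a list of
    :class:`MarkerDef` or locus names) restricts and validates the locus set;
    columns naming a locus outside the panel raise :class:`GenotypeFileError`.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = ["sample_id", "clutch_id", "year", "role"]
    for col in required:
        if col not in df.columns:
            raise GenotypeFileError(f"missing required column {col!r}")

    panel_names = None
    if panel_spec is not None:
        panel_names = [m.name if isinstance(m, MarkerDef) else str(m) for m in panel_spec]

    locus_cols = [c for c in df.columns if c not in required]
    if dialect == "wide":
        loci: list[str] = []
        for c in locus_cols:
            if c.endswith("_1"):
                locus = c[:-2]
                if f"{locus}_2" not in df.columns:
                    raise GenotypeFileError(f"locus {locus}: column {locus}_2 missing")
                loci.append(locus)
            elif c.endswith("_2"):
                continue
            else:
                raise GenotypeFileError(f"unknown locus column {c!r}")
    elif dialect == "slash":
        loci = list(locus_cols)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    if panel_names is not None:
        unknown = [l for l in loci if l not in panel_names]
        if unknown:
            raise GenotypeFileError(f"unknown loci not in panel: {unknown}")
        loci = [l for l in panel_names if l in loci]

    def parse_allele(tok: str) -> int:
        tok = tok.strip()
        if tok in ("", "NA", "na", ".", "-"):
            return MISSING
        return int(tok)

    n = len(df)
    calls: dict[str, np.ndarray] = {}
    samples = df["sample_id"].tolist()
    for locus in loci:
        arr = np.zeros((n, 2), dtype=int)
        for i in range(n):
            if dialect == "wide":
                a = parse_allele(df[f"{locus}_1"].iat[i])
                b = parse_allele(df[f"{locus}_2"].iat[i])
            else:
                tok = df[locus].iat[i].strip()
                if tok in ("", "NA", "na"):
                    a = b = MISSING
                else:
                    parts = tok.split("/")
                    if len(parts) != 2:
                        raise GenotypeFileError(
                            f"sample {samples[i]}, locus {locus}: odd allele count in {tok!r}"
                        )
                    a, b = parse_allele(parts[0]), parse_allele(parts[1])
            arr[i] = _canonical_pair(a, b, samples[i], locus)
        calls[locus] = arr

    meta = pd.DataFrame(
        {
            "clutch_id": [c if c not in ("", "NA") else None for c in df["clutch_id"]],
            "year": [int(y) if y not in ("", "NA") else None for y in df["year"]],
            "role": df["role"].tolist(),
        },
        index=pd.Index(samples, name="sample_id"),
    )
    return GenotypeTable(meta=meta, calls=calls, loci=loci)


def make_genotype_table(records, loci) -> GenotypeTable:
    """Build a table from ``(sample_id, clutch_id, year, role, {locus: pair|None})``."""
    loci = list(loci)
    ids, clutches, years, roles = [], [], [], []
    call_rows = {loc: [] for loc in loci}
    for sid, clutch, year, role, genos in records:
        ids.append(sid)
        clutches.append(clutch)
        years.append(year)
        roles.append(role)
        for loc in loci:
            pair = genos.get(loc)
            call_rows[loc].append((MISSING, MISSING) if pair is None else tuple(pair))
    meta = pd.DataFrame(
        {"clutch_id": clutches, "year": years, "role": roles},
        index=pd.Index(ids, name="sample_id"),
    )
    calls = {loc: np.array(call_rows[loc], dtype=int).reshape(len(ids), 2) for loc in loci}
    return GenotypeTable(meta=meta, calls=calls, loci=loci)


def split_by_clutch(gt: GenotypeTable, hosts: dict[str, str] | None = None) -> list[Clutch]:
    """Partition the table's embryos into clutches (sorted by clutch id)."""
    embryos = gt.meta[gt.meta["role"] == ROLE_EMBRYO]
    missing = embryos.index[embryos["clutch_id"].isna()].tolist()
    if missing:
        raise GenotypeFileError(f"embryos without clutch id: {missing}")
    clutches = []
    for cid, grp in sorted(embryos.groupby("clutch_id"), key=lambda kv: str(kv[0])):
        clutches.append(
            Clutch(
                clutch_id=str(cid),
                embryo_ids=tuple(sorted(grp.index)),
                host_species=(hosts or {}).get(str(cid)),
            )
        )
    return clutches


# ---------------------------------------------------------------------------
# mtDNA haplotypes


@dataclass
class HaplotypeAlignment:
    """Aligned control-region sequences, one per sample (equal lengths)."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise ValueError(f"sequences have unequal lengths: {sorted(lengths)}")

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values()))) if self.sequences else 0

    @classmethod
    def read_fasta(cls, path) -> "HaplotypeAlignment":
        seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
        if not seqs:
            raise ValueError(f"no sequences in {path}")
        return cls(sequences=seqs)

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for sid in sorted(self.sequences):
                fh.write(f">{sid}\n{self.sequences[sid]}\n")


@dataclass
class HaplotypeTable:
    """Sample -> haplotype label map over gap/ambiguity-stripped sequences."""

    haplotype_of: dict[str, str]
    haplotype_seqs: dict[str, str]
    stripped_length: int

    def labels_for(self, sample_ids) -> list[str | None]:
        return [self.haplotype_of.get(s) for s in sample_ids]

    def write_tsv(self, path, clutch_of: dict[str, str] | None = None) -> None:
        with open(path, "w") as fh:
            fh.write("sample_id\thaplotype\tclutch_id\n")
            for sid in sorted(self.haplotype_of):
                clutch = (clutch_of or {}).get(sid, "NA")
                fh.write(f"{sid}\t{self.haplotype_of[sid]}\t{clutch}\n")

    @classmethod
    def read_tsv(cls, path) -> "HaplotypeTable":
        df = pd.read_csv(path, sep="\t", dtype=str)
        hap_of = dict(zip(df["sample_id"], df["haplotype"]))
        return cls(haplotype_of=hap_of, haplotype_seqs={}, stripped_length=0)


def collapse_haplotypes(aln: HaplotypeAlignment, mode: str = "complete") -> HaplotypeTable:
    """Group identical sequences into haplotypes after ambiguity stripping.

    ``complete`` (default) removes every column holding a gap, ``N`` or IUPAC
    ambiguity code in *any* sequence before grouping, so one informative length
    applies to the whole alignment.  ``pairwise`` keeps all columns and joins
    samples that agree wherever both are unambiguous (transitively closed).
    Labels ``H1..Hk`` are assigned in lexicographic order of the stripped
    sequence, which makes the labelling invariant to input order and to
    duplicated samples.
    """
    if not aln.sequences:
        raise ValueError("empty alignment")
    samples = sorted(aln.sequences)
    seqs = [aln.sequences[s] for s in samples]

    if mode == "complete":
        keep = [
            j
            for j in range(aln.length)
            if all(seq[j] in _UNAMBIGUOUS for seq in seqs)
        ]
        if not keep:
            raise ValueError("no informative sites after ambiguity stripping")
        stripped = {s: "".join(aln.sequences[s][j] for j in keep) for s in samples}
        stripped_length = len(keep)
    elif mode == "pairwise":
        # union-find over samples agreeing on jointly unambiguous positions
        parent = {s: s for s in samples}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i, si in enumerate(samples):
            for sj in samples[i + 1 :]:
                a, b = aln.sequences[si], aln.sequences[sj]
                same = all(
                    ca == cb
                    for ca, cb in zip(a, b)
                    if ca in _UNAMBIGUOUS and cb in _UNAMBIGUOUS
                )
                if same:
                    parent[find(si)] = find(sj)
        groups: dict[str, list[str]] = {}
        for s in samples:
            groups.setdefault(find(s), []).append(s)
        stripped = {}
        for members in groups.values():
            rep = min(aln.sequences[m] for m in members)
            for m in members:
                stripped[m] = rep
        stripped_length = aln.length
    else:
        raise ValueError(f"unknown mode {mode!r}")

    uniq = sorted(set(stripped.values()))
    label_of_seq = {seq: f"H{i + 1}" for i, seq in enumerate(uniq)}
    return HaplotypeTable(
        haplotype_of={s: label_of_seq[stripped[s]] for s in samples},
        haplotype_seqs={label_of_seq[seq]: seq for seq in uniq},
        stripped_length=stripped_length,
    )
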
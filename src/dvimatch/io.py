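"""Readers and writers for the problem bundle and result tables.

A problem bundle is a directory (or a YAML config file) naming:

* ``frequencies`` -- TSV with columns ``marker``, ``allele``, ``freq``
  (markers ordered by first appearance);
* ``pedigrees`` -- PED-style file of the reference families;
* ``references`` -- genotype TSV of the typed family members;
* ``victims`` -- genotype TSV plus a sex declaration per victim;
* ``missing`` -- the missing persons of each family;
* ``mutation`` -- optional mutation-model settings.

Genotype TSVs have an ``individual_id`` column followed by one column per
marker, genotypes written ``a/b`` with ``-`` for missing. Result writers
produce deterministic TSVs with display rounding (log-likelihood 2 d.p.,
LR in scientific notation with 3 significant digits when large, posteriors
3 d.p.) and a JSON companion at full precision.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .genetics import FrequencyDatabase, Genotype, MutationModel
from .pedigree import FEMALE, MALE, Pedigree, format_ped, parse_ped
from .problem import DVIProblem, Family

__all__ = [
    "BundleError",
    "UnknownIDError",
    "GenotypeFormatError",
    "FrequencyError",
    "read_frequency_tsv",
    "write_frequency_tsv",
    "read_genotype_tsv",
    "write_genotype_tsv",
    "read_bundle",
    "write_bundle",
    "write_results",
    "format_lr",
]


class BundleError(ValueError):
    """Malformed or inconsistent problem bundle."""


class UnknownIDError(BundleError):
    """An ID referenced in one file does not resolve in another."""


class GenotypeFormatError(BundleError):
    """A genotype cell is not of the form 'a/b' or '-'."""


class FrequencyError(BundleError):
    """An allele-frequency table violates its invariants."""


# ---------------------------------------------------------------------------
# frequencies


def read_frequency_tsv(path: str | Path, *, renormalize: bool = False) -> FrequencyDatabase:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"frequency file not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype={"marker": str, "allele": str})
    required = {"marker", "allele", "freq"}
    if not required <= set(df.columns):
        raise FrequencyError(
            f"{path}: expected columns marker/allele/freq, got {list(df.columns)}"
        )
    data: dict[str, dict[str, float]] = {}
    for _, row in df.iterrows():
        data.setdefault(row["marker"], {})[row["allele"]] = float(row["freq"])
    try:
        return FrequencyDatabase(data, renormalize=renormalize)
    except ValueError as exc:
        raise FrequencyError(f"{path}: {exc}") from exc


def write_frequency_tsv(db: FrequencyDatabase, path: str | Path) -> None:
    rows = [
        {"marker": m, "allele": a, "freq": repr(float(f))}
        for m in db.markers
        for a, f in zip(db.alleles(m), db.freqs(m))
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# genotypes


def read_genotype_tsv(
    path: str | Path, db: FrequencyDatabase
) -> dict[str, dict[str, Genotype]]:
    """Parse a genotype TSV into ``{marker: {individual: Genotype}}``."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"genotype file not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.columns[0] != "individual_id":
        raise BundleError(f"{path}: first column must be 'individual_id'")
    out: dict[str, dict[str, Genotype]] = {}
    for marker in df.columns[1:]:
        if marker not in db:
            raise UnknownIDError(
                f"{path}: genotype column references unknown marker {marker!r}"
            )
        out[marker] = {}
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        ind = row[0]
        for marker, cell in zip(df.columns[1:], row[1:]):
            if cell is None or (isinstance(cell, float) and math.isnan(cell)):
                continue
            try:
                geno = Genotype.parse(str(cell))
            except ValueError as exc:
                raise GenotypeFormatError(f"{path}, line {lineno}: {exc}") from exc
            if geno is None:
                continue
            for allele in geno.alleles:
                try:
                    db.index(marker, allele)
                except KeyError as exc:
                    raise UnknownIDError(f"{path}, line {lineno}: {exc}") from exc
            out[marker][ind] = geno
    return out


def write_genotype_tsv(
    genotypes: Mapping[str, Mapping[str, Genotype]],
    individuals: list[str],
    markers: list[str],
    path: str | Path,
) -> None:
    rows = []
    for ind in individuals:
        row = {"individual_id": ind}
        for marker in markers:
            geno = genotypes.get(marker, {}).get(ind)
            row[marker] = str(geno) if geno is not None else "-"
        rows.append(row)
    pd.DataFrame(rows, columns=["individual_id"] + markers).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# bundles


def read_bundle(path: str | Path) -> DVIProblem:
    """Load and validate a problem bundle (directory or YAML config file)."""
    path = Path(path)
    if path.is_dir():
        for candidate in ("config.yaml", "bundle.yaml"):
            if (path / candidate).exists():
                path = path / candidate
                break
        else:
            raise FileNotFoundError(f"no config.yaml in bundle directory {path}")
    if not path.exists():
        raise FileNotFoundError(f"bundle config not found: {path}")
    base = path.parent
    cfg = yaml.safe_load(path.read_text())
    for key in ("frequencies", "pedigrees", "references", "victims", "missing"):
        if key not in cfg:
            raise BundleError(f"{path}: missing config key {key!r}")

    db = read_frequency_tsv(base / cfg["frequencies"])
    ped_path = base / cfg["pedigrees"]
    if not ped_path.exists():
        raise FileNotFoundError(f"pedigree file not found: {ped_path}")
    pedigrees = parse_ped(ped_path.read_text())
    ref_genos = read_genotype_tsv(base / cfg["references"], db)

    vcfg = cfg["victims"]
    victim_genos = read_genotype_tsv(base / vcfg["genotypes"], db)
    victim_sex = {}
    for v, s in vcfg["sex"].items():
        if s not in (MALE, FEMALE):
            raise BundleError(f"victim {v!r}: sex must be male/female, got {s!r}")
        victim_sex[str(v)] = s
    victims = tuple(victim_sex)

    mp_family: dict[str, str] = {}
    families = []
    for fid, mps in cfg["missing"].items():
        if fid not in pedigrees:
            raise UnknownIDError(f"family {fid!r} not present in pedigree file")
        ped = pedigrees[fid]
        for mp in mps:
            if mp in mp_family:
                raise BundleError(
                    f"missing person {mp!r} declared in families "
                    f"{mp_family[mp]!r} and {fid!r}"
                )
            if mp not in ped.members:
                raise UnknownIDError(f"missing person {mp!r} not in family {fid!r}")
            mp_family[mp] = fid
        members = set(ped.members)
        fam_genos = {
            marker: {ind: g for ind, g in genos.items() if ind in members}
            for marker, genos in ref_genos.items()
        }
        try:
            families.append(
                Family(fid=fid, pedigree=ped, missing=tuple(mps), genotypes=fam_genos)
            )
        except ValueError as exc:
            raise BundleError(str(exc)) from exc

    placed = {
        ind
        for fam in families
        for genos in fam.genotypes.values()
        for ind in genos
    }
    all_typed = {ind for genos in ref_genos.values() for ind in genos}
    stray = all_typed - placed
    if stray:
        raise UnknownIDError(
            f"typed reference individuals not in any family: {sorted(stray)}"
        )
    for marker, genos in victim_genos.items():
        stray = set(genos) - set(victims)
        if stray:
            raise UnknownIDError(
                f"genotyped individuals without sex declaration: {sorted(stray)}"
            )

    mcfg = cfg.get("mutation") or {"kind": "none"}
    if mcfg.get("kind", "none") == "proportional":
        model = MutationModel.proportional(db, float(mcfg.get("rate", 0.0)))
    else:
        model = MutationModel.none(db)

    try:
        return DVIProblem(
            victims=victims,
            victim_sex=victim_sex,
            victim_genotypes=victim_genos,
            families=tuple(families),
            db=db,
            model=model,
        )
    except ValueError as exc:
        raise BundleError(str(exc)) from exc


def write_bundle(problem: DVIProblem, outdir: str | Path) -> Path:
    """Write a problem as a bundle directory; returns the config path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    markers = list(problem.db.markers)
    write_frequency_tsv(problem.db, outdir / "frequencies.tsv")
    (outdir / "families.ped").write_text(
        format_ped({f.fid: f.pedigree for f in problem.families})
    )
    ref_genos: dict[str, dict[str, Genotype]] = {}
    ref_ids: list[str] = []
    for fam in problem.families:
        ref_ids.extend(fam.references)
        for marker, genos in fam.genotypes.items():
            ref_genos.setdefault(marker, {}).update(genos)
    write_genotype_tsv(ref_genos, ref_ids, markers, outdir / "references.tsv")
    write_genotype_tsv(
        problem.victim_genotypes, list(problem.victims), markers,
        outdir / "victims.tsv",
    )
    model = problem.model
    cfg = {
        "frequencies": "frequencies.tsv",
        "pedigrees": "families.ped",
        "references": "references.tsv",
        "victims": {
            "genotypes": "victims.tsv",
            "sex": {v: problem.victim_sex[v] for v in problem.victims},
        },
        "missing": {f.fid: list(f.missing) for f in problem.families},
        "mutation": {
            "kind": model.kind if model is not None else "none",
            **({"rate": model.rate} if model is not None and model.rate else {}),
        },
    }
    config_path = outdir / "config.yaml"
    config_path.write_text(yaml.safe_dump(cfg, sort_keys=False))
    return config_path


# ---------------------------------------------------------------------------
# results


def format_lr(x: float) -> str:
    """Display formatting for LR values: 3 s.f. scientific when large/tiny."""
    if x == 0.0:
        return "0.00"
    if x >= 1e5 or x < 1e-3:
        return f"{x:.2e}"
    return f"{x:.2f}"


def _format_loglik(x: float) -> str:
    return "-Inf" if x == -math.inf else f"{x:.2f}"


def _json_safe(x):
    if isinstance(x, float) and not math.isfinite(x):
        return None
    return x


def write_results(
    ranked: pd.DataFrame | None,
    posterior: pd.DataFrame | None,
    pairwise: pd.DataFrame | None,
    outdir: str | Path,
) -> None:
    """Write ranked/posterior/pairwise tables as display TSVs plus JSON.

    Any of the three tables may be None. The JSON companion
    (``results.json``) preserves full precision, with non-finite
    log-likelihoods serialized as null.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    payload: dict = {}
    if ranked is not None:
        disp = ranked.copy()
        if len(disp):
            disp["loglik"] = disp["loglik"].map(_format_loglik)
            disp["LR"] = disp["LR"].map(format_lr)
            disp["posterior"] = disp["posterior"].map(lambda q: f"{q:.3f}")
        disp.to_csv(outdir / "ranked.tsv", sep="\t", index=False)
        payload["ranked"] = [
            {k: _json_safe(v) for k, v in rec.items()}
            for rec in ranked.to_dict(orient="records")
        ]
    if posterior is not None:
        posterior.round(3).to_csv(outdir / "posterior.tsv", sep="\t")
        payload["posterior"] = {
            v: {mp: float(posterior.loc[v, mp]) for mp in posterior.columns}
            for v in posterior.index
        }
    if pairwise is not None:
        pairwise.map(format_lr).to_csv(outdir / "pairwise.tsv", sep="\t")
        payload["pairwise"] = {
            v: {mp: float(pairwise.loc[v, mp]) for mp in pairwise.columns}
            for v in pairwise.index
        }
    (outdir / "results.json").write_text(json.dumps(payload, indent=1))
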
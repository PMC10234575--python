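"""Constraint-based analysis of genome-scale metabolic models.

Flux balance analysis (FBA) maximizes a biomass objective c.v subject to
steady-state mass balance S.v = 0 and flux bounds lb <= v <= ub. Parsimonious
FBA (pFBA) fixes the objective at its optimum and minimizes total absolute
flux; flux variability analysis (FVA) reports per-reaction flux ranges
compatible with near-optimal growth. On top of these, the module converts
defined-media concentrations into uptake bounds, sweeps leave-one-out media
and single-reaction knockouts, and scores concordance of predictions against
growth, metabolomics, expression, and gene-conservation data.

All linear programs are solved with the deterministic HiGHS solver via
scipy.optimize.linprog.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.stats.contingency import odds_ratio as _odds_ratio

GROWTH_EPS = 1e-6  # growth/no-growth binarization threshold (1/h)
ACTIVE_EPS = 1e-9  # |flux| above which a reaction counts as active
DEFAULT_BOUND = 1000.0


# ---------------------------------------------------------------------------
# model types
# ---------------------------------------------------------------------------

@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    gpr: str = ""
    subsystem: str = ""
    name: str = ""

    @property
    def is_exchange(self) -> bool:
        return len(self.stoichiometry) == 1

    def genes(self) -> list[str]:
        out = []
        for tok in self.gpr.replace("(", " ").replace(")", " ").split():
            if tok.lower() in {"and", "or"}:
                continue
            out.append(tok)
        return sorted(set(out))


@dataclass
class MetabolicModel:
    id: str
    metabolites: dict[str, Metabolite]
    reactions: dict[str, Reaction]
    objective_reaction_id: str
    genes: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for rxn in self.reactions.values():
            for met in rxn.stoichiometry:
                if met not in self.metabolites:
                    raise ValueError(f"reaction {rxn.id}: unknown metabolite {met}")
            if rxn.lower_bound > rxn.upper_bound:
                raise ValueError(f"reaction {rxn.id}: lower_bound > upper_bound")
        if self.objective_reaction_id not in self.reactions:
            raise ValueError(
                f"objective reaction {self.objective_reaction_id!r} not in model"
            )
        if not self.genes:
            self.genes = {g for r in self.reactions.values() for g in r.genes()}

    # -- structure ----------------------------------------------------
    @property
    def reaction_ids(self) -> list[str]:
        return list(self.reactions)

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.metabolites)

    def exchange_reactions(self) -> list[str]:
        return [r.id for r in self.reactions.values() if r.is_exchange]

    def stoichiometric_matrix(self) -> np.ndarray:
        mets = {m: i for i, m in enumerate(self.metabolite_ids)}
        S = np.zeros((len(mets), len(self.reactions)))
        for j, rxn in enumerate(self.reactions.values()):
            for met, coef in rxn.stoichiometry.items():
                S[mets[met], j] = coef
        return S

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            id=self.id,
            metabolites={k: Metabolite(v.id, v.name, v.compartment) for k, v in self.metabolites.items()},
            reactions={
                k: Reaction(v.id, dict(v.stoichiometry), v.lower_bound, v.upper_bound,
                            v.gpr, v.subsystem, v.name)
                for k, v in self.reactions.items()
            },
            objective_reaction_id=self.objective_reaction_id,
            genes=set(self.genes),
        )

    def exchange_for_metabolite(self, met_id: str) -> str | None:
        for r in self.reactions.values():
            if r.is_exchange and met_id in r.stoichiometry:
                return r.id
        return None


@dataclass
class MediaDefinition:
    """Defined-media composition plus the conversion constants to uptake rates.

    ``quantitative`` maps exchange-reaction id -> concentration in mM;
    ``qualitative`` compounds (detected in media but unquantified) get a
    fixed uptake allowance. ``cell_dry_weight`` (g/cell) times cell count
    gives biomass density in gDW/L; duration is the exponential window in
    hours over which the media is consumed.
    """

    quantitative: dict[str, float]
    qualitative: set[str] = field(default_factory=set)
    biomass_density: float = 0.01  # gDW/L
    duration: float = 24.0  # h
    cell_dry_weight: float = 3.3e-13  # g/cell

    def __post_init__(self) -> None:
        if self.biomass_density <= 0:
            raise ValueError("biomass_density must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        for cid, conc in self.quantitative.items():
            if conc < 0:
                raise ValueError(f"negative concentration for {cid}")

    def uptake_rate(self, concentration_mM: float) -> float:
        """mM -> mmol/gDW/h: U = C / (X * dt)."""
        return concentration_mM / (self.biomass_density * self.duration)

    @classmethod
    def from_tsv(cls, path: str | Path, **kwargs) -> "MediaDefinition":
        df = pd.read_csv(path, sep="\t")
        quant: dict[str, float] = {}
        qual: set[str] = set()
        for _, row in df.iterrows():
            ex = row["exchange_id"]
            if bool(row.get("qualitative", False)):
                qual.add(ex)
            else:
                quant[ex] = float(row["concentration_mM"])
        return cls(quantitative=quant, qualitative=qual, **kwargs)


@dataclass
class FluxSolution:
    status: str  # optimal / infeasible
    mu: float | None
    fluxes: dict[str, float]

    def flux_series(self) -> pd.Series:
        return pd.Series(self.fluxes)


@dataclass
class FvaRange:
    reaction_id: str
    min_flux: float
    max_flux: float
    fraction_of_optimum: float = 0.99


@dataclass
class ConfusionSummary:
    tp: int
    fp: int
    fn: int
    tn: int
    mcc: float
    odds_ratio: float
    fisher_p: float


@dataclass
class KnockoutResult:
    reaction_id: str
    mu_ko: float
    category: str  # essential / reduced / neutral
    below_70pct: bool


# ---------------------------------------------------------------------------
# model I/O
# ---------------------------------------------------------------------------

def load_model(path: str | Path, dialect: str | None = None) -> MetabolicModel:
    """Load a model from SBML Level 3 (FBC) or the package's JSON dialect."""
    path = Path(path)
    if dialect is None:
        dialect = "json" if path.suffix == ".json" else "sbml-fbc"
    if dialect == "json":
        return _model_from_json(json.loads(path.read_text()))
    if dialect == "sbml-fbc":
        return _model_from_sbml(path)
    raise ValueError(f"unknown model dialect {dialect!r}")


def save_model(model: MetabolicModel, path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(_model_to_json(model), indent=1, sort_keys=True))
    else:
        _model_to_sbml(model, path)


def _model_to_json(model: MetabolicModel) -> dict:
    return {
        "id": model.id,
        "metabolites": [
            {"id": m.id, "name": m.name, "compartment": m.compartment}
            for m in model.metabolites.values()
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "stoichiometry": r.stoichiometry,
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "gpr": r.gpr,
                "subsystem": r.subsystem,
            }
            for r in model.reactions.values()
        ],
        "genes": sorted(model.genes),
        "objective": model.objective_reaction_id,
    }


def _model_from_json(data: dict) -> MetabolicModel:
    if "objective" not in data or not data["objective"]:
        raise ValueError("model JSON missing objective reaction")
    mets = {
        m["id"]: Metabolite(m["id"], m.get("name", ""), m.get("compartment", "c"))
        for m in data["metabolites"]
    }
    rxns = {}
    for r in data["reactions"]:
        stoich = {k: float(v) for k, v in r["stoichiometry"].items()}
        rxns[r["id"]] = Reaction(
            r["id"], stoich,
            float(r.get("lower_bound", -DEFAULT_BOUND)),
            float(r.get("upper_bound", DEFAULT_BOUND)),
            r.get("gpr", ""), r.get("subsystem", ""), r.get("name", ""),
        )
    return MetabolicModel(
        id=data.get("id", "model"),
        metabolites=mets,
        reactions=rxns,
        objective_reaction_id=data["objective"],
        genes=set(data.get("genes", [])),
    )


def _model_from_sbml(path: Path) -> MetabolicModel:
    import libsbml

    doc = libsbml.readSBMLFromString(Path(path).read_text())
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        raise ValueError(f"SBML parse error in {path}: {doc.getError(0).getMessage()}")
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise ValueError(f"no model element in {path}")
    fbc = sbml_model.getPlugin("fbc")

    mets = {}
    for i in range(sbml_model.getNumSpecies()):
        sp = sbml_model.getSpecies(i)
        if sp.getBoundaryCondition():
            continue
        mets[sp.getId()] = Metabolite(sp.getId(), sp.getName() or "", sp.getCompartment() or "c")

    params = {
        sbml_model.getParameter(i).getId(): sbml_model.getParameter(i).getValue()
        for i in range(sbml_model.getNumParameters())
    }

    def _gpr_string(assoc) -> str:
        if assoc is None:
            return ""
        if assoc.isFbcAnd():
            return "(" + " and ".join(_gpr_string(assoc.getAssociation(i)) for i in range(assoc.getNumAssociations())) + ")"
        if assoc.isFbcOr():
            return "(" + " or ".join(_gpr_string(assoc.getAssociation(i)) for i in range(assoc.getNumAssociations())) + ")"
        return assoc.getGeneProduct()

    gene_products = {}
    if fbc is not None:
        for i in range(fbc.getNumGeneProducts()):
            gp = fbc.getGeneProduct(i)
            gene_products[gp.getId()] = gp.getLabel() or gp.getId()

    rxns = {}
    for i in range(sbml_model.getNumReactions()):
        rx = sbml_model.getReaction(i)
        stoich: dict[str, float] = {}
        for j in range(rx.getNumReactants()):
            sr = rx.getReactant(j)
            if sr.getSpecies() in mets:
                stoich[sr.getSpecies()] = stoich.get(sr.getSpecies(), 0.0) - sr.getStoichiometry()
        for j in range(rx.getNumProducts()):
            sr = rx.getProduct(j)
            if sr.getSpecies() in mets:
                stoich[sr.getSpecies()] = stoich.get(sr.getSpecies(), 0.0) + sr.getStoichiometry()
        rfbc = rx.getPlugin("fbc")
        lb, ub = -DEFAULT_BOUND, DEFAULT_BOUND
        gpr = ""
        if rfbc is not None:
            lb = params.get(rfbc.getLowerFluxBound(), lb)
            ub = params.get(rfbc.getUpperFluxBound(), ub)
            ga = rfbc.getGeneProductAssociation()
            if ga is not None:
                raw = _gpr_string(ga.getAssociation())
                for gid, label in gene_products.items():
                    raw = raw.replace(gid, label)
                gpr = raw
        rxns[rx.getId()] = Reaction(rx.getId(), stoich, lb, ub, gpr, "", rx.getName() or "")

    objective = None
    if fbc is not None and fbc.getNumObjectives() > 0:
        obj = fbc.getObjective(fbc.getActiveObjectiveId()) or fbc.getObjective(0)
        if obj.getNumFluxObjectives() > 0:
            objective = obj.getFluxObjective(0).getReaction()
    if objective is None:
        raise ValueError(f"SBML model {path} declares no FBC objective")
    return MetabolicModel(
        id=sbml_model.getId() or "model",
        metabolites=mets,
        reactions=rxns,
        objective_reaction_id=objective,
        genes=set(gene_products.values()),
    )


def _model_to_sbml(model: MetabolicModel, path: Path) -> None:
    import libsbml

    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sm = doc.createModel()
    sm.setId(model.id)
    mplug = sm.getPlugin("fbc")
    mplug.setStrict(True)

    comps = sorted({m.compartment for m in model.metabolites.values()})
    for cid in comps:
        c = sm.createCompartment()
        c.setId(cid)
        c.setConstant(True)
    for m in model.metabolites.values():
        sp = sm.createSpecies()
        sp.setId(m.id)
        sp.setName(m.name)
        sp.setCompartment(m.compartment)
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)

    genes = sorted(model.genes)
    gid_of = {}
    for g in genes:
        gp = mplug.createGeneProduct()
        gid = "G_" + "".join(ch if ch.isalnum() else "_" for ch in g)
        gp.setId(gid)
        gp.setLabel(g)
        gid_of[g] = gid

    bound_params = {}

    def _param(value: float) -> str:
        key = f"{value:.12g}"
        if key not in bound_params:
            pid = f"fb_{len(bound_params)}"
            p = sm.createParameter()
            p.setId(pid)
            p.setValue(value)
            p.setConstant(True)
            bound_params[key] = pid
        return bound_params[key]

    for r in model.reactions.values():
        rx = sm.createReaction()
        rx.setId(r.id)
        rx.setName(r.name)
        rx.setFast(False)
        rx.setReversible(r.lower_bound < 0)
        for met, coef in r.stoichiometry.items():
            sr = rx.createReactant() if coef < 0 else rx.createProduct()
            sr.setSpecies(met)
            sr.setStoichiometry(abs(coef))
            sr.setConstant(True)
        rplug = rx.getPlugin("fbc")
        rplug.setLowerFluxBound(_param(r.lower_bound))
        rplug.setUpperFluxBound(_param(r.upper_bound))
        if r.gpr:
            ga = rplug.createGeneProductAssociation()
            infix = r.gpr
            for g, gid in gid_of.items():
                infix = infix.replace(g, gid)
            ga.setAssociation(infix)

    obj = mplug.createObjective()
    obj.setId("obj")
    obj.setType("maximize")
    fo = obj.createFluxObjective()
    fo.setReaction(model.objective_reaction_id)
    fo.setCoefficient(1.0)
    mplug.setActiveObjectiveId("obj")
    libsbml.writeSBMLToFile(doc, str(path))


# ---------------------------------------------------------------------------
# media -> bounds
# ---------------------------------------------------------------------------

def media_to_bounds(
    model: MetabolicModel,
    media: MediaDefinition,
    qualitative_bound: float = 1.0,
) -> tuple[MetabolicModel, list[str]]:
    """Constrain exchange lower bounds from a media definition.

    Quantified compounds get max uptake U = C / (X * dt) in mmol/gDW/h;
    qualitative compounds get ``qualitative_bound`` (1 mmol/gDW/h by
    default); every unlisted exchange is closed to uptake. Secretion bounds
    are untouched. Returns the constrained model and the list of media
    entries with no matching exchange reaction (skipped with a warning).
    """
    out = model.copy()
    exchanges = set(out.exchange_reactions())
    missing = []
    for ex in exchanges:
        out.reactions[ex].lower_bound = 0.0
    for ex, conc in media.quantitative.items():
        if ex not in exchanges:
            missing.append(ex)
            continue
        out.reactions[ex].lower_bound = -media.uptake_rate(conc)
    for ex in media.qualitative:
        if ex not in exchanges:
            missing.append(ex)
            continue
        out.reactions[ex].lower_bound = -qualitative_bound
    return out, missing


# ---------------------------------------------------------------------------
# LP core
# ---------------------------------------------------------------------------

def _lp_parts(model: MetabolicModel):
    rids = model.reaction_ids
    S = model.stoichiometric_matrix()
    lb = np.array([model.reactions[r].lower_bound for r in rids])
    ub = np.array([model.reactions[r].upper_bound for r in rids])
    c = np.zeros(len(rids))
    c[rids.index(model.objective_reaction_id)] = 1.0
    return rids, S, lb, ub, c


def fba(model: MetabolicModel) -> FluxSolution:
    """Maximize the objective flux subject to S.v = 0 and bounds."""
    rids, S, lb, ub, c = _lp_parts(model)
    res = optimize.linprog(
        -c, A_eq=S, b_eq=np.zeros(S.shape[0]),
        bounds=list(zip(lb, ub)), method="highs",
    )
    if not res.success:
        return FluxSolution(status="infeasible", mu=None, fluxes={})
    fluxes = dict(zip(rids, res.x))
    return FluxSolution(status="optimal", mu=float(-res.fun), fluxes=fluxes)


def pfba(model: MetabolicModel) -> FluxSolution:
    """Minimize total |v| at the fixed FBA optimum (variables [v, t], t >= |v|)."""
    base = fba(model)
    if base.status != "optimal":
        return base
    rids, S, lb, ub, c = _lp_parts(model)
    n = len(rids)
    # equality: S v = 0 and c.v = mu*
    A_eq = np.zeros((S.shape[0] + 1, 2 * n))
    A_eq[: S.shape[0], :n] = S
    A_eq[-1, :n] = c
    b_eq = np.zeros(S.shape[0] + 1)
    b_eq[-1] = base.mu
    # inequalities: v - t <= 0 ; -v - t <= 0
    A_ub = np.zeros((2 * n, 2 * n))
    A_ub[:n, :n] = np.eye(n)
    A_ub[:n, n:] = -np.eye(n)
    A_ub[n:, :n] = -np.eye(n)
    A_ub[n:, n:] = -np.eye(n)
    bounds = list(zip(lb, ub)) + [(0.0, None)] * n
    cost = np.concatenate([np.zeros(n), np.ones(n)])
    res = optimize.linprog(
        cost, A_ub=A_ub, b_ub=np.zeros(2 * n), A_eq=A_eq, b_eq=b_eq,
        bounds=bounds, method="highs",
    )
    if not res.success:
        return FluxSolution(status="infeasible", mu=None, fluxes={})
    return FluxSolution(status="optimal", mu=base.mu, fluxes=dict(zip(rids, res.x[:n])))


def fva(model: MetabolicModel, fraction: float = 0.99) -> list[FvaRange]:
    """Per-reaction min/max flux with objective >= fraction * mu*."""
    base = fba(model)
    if base.status != "optimal" or base.mu is None or base.mu <= GROWTH_EPS:
        raise ValueError("FVA requires an optimal FBA solution with mu > 0")
    rids, S, lb, ub, c = _lp_parts(model)
    A_ub = -c.reshape(1, -1)
    b_ub = np.array([-fraction * base.mu])
    bounds = list(zip(lb, ub))
    out = []
    for j, rid in enumerate(rids):
        obj = np.zeros(len(rids))
        obj[j] = 1.0
        lo = optimize.linprog(obj, A_ub=A_ub, b_ub=b_ub, A_eq=S,
                              b_eq=np.zeros(S.shape[0]), bounds=bounds, method="highs")
        hi = optimize.linprog(-obj, A_ub=A_ub, b_ub=b_ub, A_eq=S,
                              b_eq=np.zeros(S.shape[0]), bounds=bounds, method="highs")
        if not (lo.success and hi.success):
            raise ValueError(f"FVA infeasible for reaction {rid} at fraction {fraction}")
        out.append(FvaRange(rid, float(lo.fun), float(-hi.fun), fraction))
    return out


# ---------------------------------------------------------------------------
# sweeps
# ---------------------------------------------------------------------------

def simulate_leave_one_out(
    model: MetabolicModel,
    media: MediaDefinition,
    compounds: list[str] | None = None,
    qualitative_bound: float = 1.0,
) -> dict[str, float | None]:
    """Predicted max growth rate with each media compound removed in turn.

    ``compounds`` are exchange ids present in the media; removal closes that
    exchange to uptake. Infeasible conditions report ``None``.
    """
    if compounds is None:
        compounds = sorted(set(media.quantitative) | set(media.qualitative))
    unknown = [c for c in compounds if c not in media.quantitative and c not in media.qualitative]
    if unknown:
        raise ValueError(f"compounds not in media: {unknown}")
    out: dict[str, float | None] = {}
    for comp in compounds:
        reduced = MediaDefinition(
            quantitative={k: v for k, v in media.quantitative.items() if k != comp},
            qualitative={q for q in media.qualitative if q != comp},
            biomass_density=media.biomass_density,
            duration=media.duration,
            cell_dry_weight=media.cell_dry_weight,
        )
        constrained, _ = media_to_bounds(model, reduced, qualitative_bound)
        sol = fba(constrained)
        out[comp] = sol.mu if sol.status == "optimal" else None
    return out


def growth_confusion(
    predicted: dict[str, bool], observed: dict[str, bool]
) -> ConfusionSummary:
    """2x2 agreement of predicted vs observed growth with MCC and Fisher test."""
    keys = sorted(set(predicted) & set(observed))
    if len(keys) < 2:
        raise ValueError("growth confusion requires >= 2 shared conditions")
    tp = sum(predicted[k] and observed[k] for k in keys)
    fp = sum(predicted[k] and not observed[k] for k in keys)
    fn = sum(not predicted[k] and observed[k] for k in keys)
    tn = sum(not predicted[k] and not observed[k] for k in keys)
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = 0.0 if denom == 0 else (tp * tn - fp * fn) / denom
    table = [[tp, fp], [fn, tn]]
    _, fisher_p = stats.fisher_exact(table, alternative="two-sided")
    try:
        orr = float(_odds_ratio(table, kind="conditional").statistic)
    except ValueError:
        orr = math.inf
    return ConfusionSummary(tp, fp, fn, tn, float(mcc), orr, float(fisher_p))


def single_reaction_knockouts(
    model: MetabolicModel, reactions: list[str] | None = None
) -> list[KnockoutResult]:
    """Zero both bounds of each reaction and re-run FBA.

    Categories: essential (mu_ko <= 1e-6), reduced (between 1e-6 and
    mu_wt - 1e-6), neutral otherwise; the <70%-of-wild-type flag marks the
    substantial-growth-effect set used for conservation comparisons.
    """
    wt = fba(model)
    if wt.status != "optimal" or wt.mu is None or wt.mu <= GROWTH_EPS:
        raise ValueError("knockout sweep requires wild-type growth")
    mu_wt = wt.mu
    out = []
    for rid in reactions if reactions is not None else model.reaction_ids:
        ko = model.copy()
        ko.reactions[rid].lower_bound = 0.0
        ko.reactions[rid].upper_bound = 0.0
        sol = fba(ko)
        mu_ko = sol.mu if sol.status == "optimal" and sol.mu is not None else 0.0
        if mu_ko <= GROWTH_EPS:
            category = "essential"
        elif mu_ko < mu_wt - GROWTH_EPS:
            category = "reduced"
        else:
            category = "neutral"
        out.append(KnockoutResult(rid, float(mu_ko), category, mu_ko < 0.7 * mu_wt))
    return out


# ---------------------------------------------------------------------------
# concordance scoring
# ---------------------------------------------------------------------------

def fva_exchange_concordance(
    fva_ranges: list[FvaRange],
    differential_calls: dict[str, str],
    metabolite_exchange: dict[str, str],
) -> tuple[float, pd.DataFrame]:
    """Compatibility of FVA exchange ranges with metabolomics shift calls.

    A metabolite is compatible iff: an import-only range (max_flux <= 0)
    coincides with an experimental decrease, and an experimental increase
    coincides with secretion potential (max_flux > 0). Unmapped metabolites
    are reported, not fatal. Returns (fraction compatible, verdict table).
    """
    ranges = {r.reaction_id: r for r in fva_ranges}
    rows = []
    for met, call in differential_calls.items():
        ex = metabolite_exchange.get(met)
        if ex is None or ex not in ranges:
            rows.append(dict(metabolite=met, call=call, verdict="unmapped",
                             min_flux=np.nan, max_flux=np.nan))
            continue
        r = ranges[ex]
        compatible = True
        if r.max_flux <= 0 and call != "decreased":
            compatible = False
        if call == "increased" and not r.max_flux > 0:
            compatible = False
        rows.append(dict(metabolite=met, call=call,
                         verdict="compatible" if compatible else "incompatible",
                         min_flux=r.min_flux, max_flux=r.max_flux))
    df = pd.DataFrame(rows)
    scored = df[df["verdict"] != "unmapped"]
    frac = float((scored["verdict"] == "compatible").mean()) if len(scored) else float("nan")
    return frac, df


def flux_expression_concordance(
    solution: FluxSolution,
    expression: dict[str, float],
    model: MetabolicModel,
) -> dict[str, float]:
    """Concordance of pFBA activity with metabolic gene expression.

    Gene-reaction pairs are enumerated via GPR rules (a gene in several
    reactions is counted once per pairing). A pair is active when the linked
    reaction carries |flux| > 1e-9. Reports the fraction of active and
    inactive pairs whose gene is in the top half of metabolic-gene
    expression, their ratio, a two-sided Fisher p for the 2x2, and the
    Spearman correlation of expression with |flux| over pairs.
    """
    pairs = []  # (gene, reaction)
    for rid, rxn in model.reactions.items():
        for g in rxn.genes():
            if g in expression:
                pairs.append((g, rid))
    if len(pairs) < 10:
        raise ValueError("need >= 10 gene-reaction pairs with expression data")
    expr_genes = sorted({g for g, _ in pairs})
    levels = np.array([expression[g] for g in expr_genes])
    median = float(np.median(levels))
    top_half = {g: expression[g] > median for g in expr_genes}

    active_top = inactive_top = n_active = n_inactive = 0
    xs, ys = [], []
    for g, rid in pairs:
        act = abs(solution.fluxes.get(rid, 0.0)) > ACTIVE_EPS
        xs.append(expression[g])
        ys.append(abs(solution.fluxes.get(rid, 0.0)))
        if act:
            n_active += 1
            active_top += top_half[g]
        else:
            n_inactive += 1
            inactive_top += top_half[g]
    af = active_top / n_active if n_active else float("nan")
    inf_ = inactive_top / n_inactive if n_inactive else float("nan")
    table = [
        [active_top, n_active - active_top],
        [inactive_top, n_inactive - inactive_top],
    ]
    if n_active and n_inactive:
        _, p = stats.fisher_exact(table, alternative="two-sided")
    else:
        p = float("nan")
    rho = stats.spearmanr(xs, ys).statistic if len(set(ys)) > 1 else float("nan")
    ratio = af / inf_ if (n_inactive and inf_ > 0) else (1.0 if n_inactive == 0 else float("inf"))
    return dict(
        active_top_half_frac=float(af),
        inactive_top_half_frac=float(inf_),
        ratio=float(ratio),
        enrichment_p=float(p),
        spearman_rho=float(rho),
    )


def knockout_conservation_test(
    knockouts: list[KnockoutResult],
    model: MetabolicModel,
    gene_presence_fraction: dict[str, float],
    core_membership: dict[str, bool],
) -> dict[str, float]:
    """Are genes behind growth-reducing knockouts more conserved across strains?

    Genes are partitioned by whether any linked reaction's knockout drops
    growth below 70% of wild type. Reports a Wilcoxon rank-sum p on strain
    presence fractions between partitions, and a Fisher exact test (with
    conditional-MLE odds ratio) on core-genome membership.
    """
    effect_rxns = {k.reaction_id for k in knockouts if k.below_70pct}
    effect_genes: set[str] = set()
    other_genes: set[str] = set()
    for rid, rxn in model.reactions.items():
        for g in rxn.genes():
            (effect_genes if rid in effect_rxns else other_genes).add(g)
    other_genes -= effect_genes
    eff = [gene_presence_fraction[g] for g in sorted(effect_genes) if g in gene_presence_fraction]
    oth = [gene_presence_fraction[g] for g in sorted(other_genes) if g in gene_presence_fraction]
    if not eff or not oth:
        raise ValueError("one knockout-effect partition is empty")
    wstat = stats.mannwhitneyu(eff, oth, alternative="two-sided")
    a = sum(core_membership.get(g, False) for g in effect_genes)
    b = len(effect_genes) - a
    cc = sum(core_membership.get(g, False) for g in other_genes)
    d = len(other_genes) - cc
    table = [[a, b], [cc, d]]
    _, fisher_p = stats.fisher_exact(table, alternative="two-sided")
    if b == 0 or cc == 0:
        orr = math.inf  # degenerate table: all effect genes core
    else:
        try:
            orr = float(_odds_ratio(table, kind="conditional").statistic)
        except ValueError:
            orr = math.inf
    return dict(wilcoxon_p=float(wstat.pvalue), fisher_or=orr, fisher_p=float(fisher_p))
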
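# pahfire

A desk-scale, fully tested pipeline quantifying the wildfire contribution to
polycyclic aromatic hydrocarbon (PAH) concentrations and incremental lifetime
cancer risk (ILCR):

- **species_registry** — the 16 EPA priority parent PAHs plus 6 nitro/dinitro
  degradation products with per-species chemistry and toxicity parameters
  (TEQ, rate constants, ppLFER partitioning descriptors), loaded from an
  overridable CSV table.
- **emissions** — sector × species × month × grid inventory model; fire-sector
  speciation redistribution (all non-NAP fire mass moved onto the 3-/4-ring
  species, preserving relative proportions and conserving the total),
  no-wildfire scenario construction, sector ring-size composition.
- **fate_boxmodel** — per-cell box model: gas-phase emission, equilibrium
  gas/particle partitioning (poly-parameter linear free energy form), OH/NO3
  photooxidation, heterogeneous ozonolysis, deposition, and NPAH/DNPAH
  diagnosis from the steady-state nitro-pyrene pathway ratio broadcast to all
  parents. Exact exponential within-step updates; linear in emissions, so
  scenario differencing obeys superposition.
- **attribution** — baseline − no-wildfire differencing, area-weighted
  regional summaries, phase/product composition, meteorology differencing.
- **health_risk** — gridded ILCR (unit risk × concentration × TEQ, same TEQ
  across phases), toxicity per unit mass (TPUM), 1.0e-6 threshold exceedance,
  and fire-risk decomposition by phase and degradation class.
- **evaluation** — observation-to-grid pairing and normalized mean bias
  (per species and LMW/HMW classes).
- **synthetic_data** — seeded generators for every input (inventories with
  fire-prone regional/seasonal structure, co-located PM and oxidant
  enhancements, noisy observations), so the whole pipeline runs offline.

## CLI

```sh
pahfire synth --outdir bundle --seed 0        # write synthetic inputs + starter config
pahfire simulate  --config bundle/run_config.yaml
pahfire attribute --config bundle/run_config.yaml
pahfire risk      --config bundle/run_config.yaml
pahfire evaluate  --config bundle/run_config.yaml
pahfire all       --config bundle/run_config.yaml   # one-shot pipeline
```

`simulate` writes annual-mean concentration states for baseline and
no-wildfire scenarios for a low- and a high-fire year; `risk` writes
`report.json` with the fire share of concentration and ILCR, phase fractions,
NPAH/DNPAH shares, TPUM for all/fire/non-fire mixtures, and exceedance
counts. The config's `mode` selects `scenario-oxidant` (default; the
no-wildfire run also loses the fire-driven PM/oxidant enhancements) or
`shared-oxidant` (both runs share the baseline environment, making the
attribution a pure emission effect that obeys superposition exactly).

Exit codes: 0 ok, 1 user error (bad config/missing inputs), 2 internal error.

## Notes

- Default species parameters (TEQs, rate constants, partitioning
  descriptors) are documented, provenance-annotated defaults in
  `src/pahfire/data/species_default.csv`; override any of them by pointing a
  run config at a replacement table.
- The box model deliberately omits transport (independent columns) and
  interactive oxidant chemistry; it is a stand-in for a full chemical
  transport model that keeps the attribution, partitioning, and risk logic
  testable at desk scale.
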
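# seegplan

Experience-based planning support for stereo-electroencephalography (SEEG).

SEEG localises the epileptogenic zone of drug-resistant focal epilepsy by
implanting many intracerebral electrodes, and planning their trajectories is
slow, manual work.  Existing automated planners optimise trajectories
against geometric constraints but cannot propose the *initial* electrode
set.  `seegplan` mines a centre's retrospective plans into that missing
starting point:

1. **Descriptors** — each trajectory is classified by the atlas zones it
   enters and targets, `d = [Z_EP^a; Z_TP^b]`; same-descriptor trajectories
   across patients form an *exploratory pattern* `pt_{a,b}`.
2. **Mean trajectories** — each pattern is compressed in a common average
   brain space by iterative k-means on joint (EP, TP) coordinates, starting
   from `U_{a,b}` (the most same-pattern electrodes any single plan used)
   and decrementing k until every cluster holds ≥ 5% of the pattern; each
   cluster yields a mean trajectory `mT_{a,b}^u` with RMS dispersions
   σ_ep, σ_tp.
3. **Planning strategies** — plans become boolean vectors `f_j` over the mT
   list, are clustered hierarchically with Jaccard distance, and each group
   keeps the bits supported by ≥ 2 member plans, giving strategies `cl_g`.
4. **Initialisation** — a chosen strategy is mapped into a new subject
   through the inverse registration affine; against a manual plan, paired
   trajectories count as *correctly mapped* when `d_ep ≤ 2σ(mT^ep)` and
   `d_tp ≤ 2σ(mT^tp)`.

Because clinical planning data cannot be shared, the package ships a
synthetic-cohort generator with planted ground truth (strategies, mean
trajectories, per-subject affines, block-structured atlas) so the entire
pipeline is testable end-to-end.  See `docs/methods.md` for the model,
assumptions and limitations.

## Worked example

```sh
seegplan simulate --seed 11 --out cohort/
seegplan build-model --plans cohort/plans.csv --atlas cohort/atlas.nii \
    --lut cohort/atlas_lut.txt --xfm-dir cohort/xfm --zones cohort/zones.json \
    --seed 11 --out model.json
seegplan cluster-strategies --model model.json --cut 0.7 --out model.json
seegplan init-plan --model model.json --strategy S1 \
    --xfm cohort/xfm/P000.mat --patient-id P000 --out ip.csv
```

The same flow from Python, with the numbers it prints:

```python
from seegplan import (CohortSpec, generate_atlas, generate_cohort,
                      build_model_bundle, add_strategies)

spec = CohortSpec(seed=11)                      # 40 plans, 4 planted strategies
volume, zones = generate_atlas(spec)
plans, affines, truth = generate_cohort(spec)
bundle = build_model_bundle(plans, affines, volume, zones, seed=11)
add_strategies(bundle, cut_threshold=0.7)
print(len(bundle.mean_trajectories), len(bundle.strategies))
# 12 4
mt = bundle.mean_trajectories[0]
print(mt.descriptor, mt.n_members, round(mt.sigma_entry, 2))
# Descriptor(entry_zone=100, target_zone=200) 10 3.52
```

`12 4`: the miner recovered all 12 planted mean trajectories and the 4
planted strategies.  The first mean trajectory averages 10 member
trajectories whose entry points scatter with a 3.52 mm RMS radius around
the centroid — that radius is the σ used by the 2σ mapping-validation
criterion.  Each `seegplan` subcommand writes plain inspectable artifacts
(CSV trajectory tables, a JSON model bundle, 4×4 text affines, NIfTI
labels).

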
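# crowdseg

Quality-control engine for crowdsourced pixel-level binary segmentation.
It implements the full scoring pipeline behind a gamified, continuously
performance-monitored annotation campaign:

- **Gating** — annotator qualification by training score (TS, mean IoU
  against a fixed set of expert gold tasks) and continuous monitoring by a
  running score (RS, rolling IoU over gold tests interleaved into the task
  stream). Disqualification is prospective only.
- **Consensus** — pixel-wise majority-vote fusion of the qualified
  annotations of each (frame, structure) task, with an absolute per-pixel
  vote threshold (MV) and a minimum annotation count (n).
- **Difficulty & QA** — a per-task difficulty index
  (DI = 1 − mean IoU of each contributing annotation vs the consensus),
  review-threshold (RT) flagging of hard tasks, and Bernoulli sampling of
  flagged tasks for expert review.
- **Metrics** — IoU, F1/Dice, accuracy, sensitivity, specificity from one
  confusion computation, with macro-averaged mean ± sd cohort summaries.
  Unanimous "no finding" (both masks empty) counts as perfect agreement.
- **Campaign accounting** — a ledger of individual / consensus / pending /
  gold-test annotations, QA counts, expert hours saved, and expert
  throughput, plus annotator-demographics summaries.
- **Simulator** — synthetic ground-truth scenes (random discs, with
  structure-absent frames yielding "no finding") and skill-parameterized
  synthetic annotators (boundary jitter, boundary pixel noise, miss
  probability, spammers), so the whole pipeline runs end-to-end with known
  truth and no external data. All randomness is hierarchically seeded and
  reproducible.

The shipped default configuration uses two structure tasks
(`bowel`: n = 5, MV = 4; `abdominal_wall`: n = 5, MV = 2), RT = 0.4,
10 training gold tasks, and 120.3 expert-seconds per frame. The TS/RS
cutoffs (0.5/0.5), RS cadence (1 gold per 20 tasks) and RS window (10) are
explicit repo defaults, overridable in the config.

## Library quick start

```python
import crowdseg as cs

scene = cs.SceneSpec(
    width=32, height=32,
    structures={
        "bowel": {"presence_probability": 0.7, "blob_radius": (3, 8)},
        "abdominal_wall": {"presence_probability": 0.8, "blob_radius": (3, 8)},
    },
)
pool = cs.uniform_pool(6, scene, n_frames=100, boundary_jitter=1,
                       pixel_noise=0.02, seed=0)
result = cs.run_campaign(pool.tasks, pool, cs.default_config(seed=0))
print(result.ledger)
print(cs.difficulty_profile(result.difficulty_records))
```

## CLI

```sh
crowdseg simulate  --scene scene.yaml --pool pool.yaml --frames 50 --seed 1 --out sim/
crowdseg gate      --manifest sim/manifest.csv --refs sim/references.csv \
                   --config config.yaml --out profiles.csv
crowdseg consensus --manifest sim/manifest.csv --config config.yaml --out consensus/
crowdseg difficulty --consensus consensus/ --manifest sim/manifest.csv \
                    --config config.yaml --out difficulty.csv
crowdseg eval      --pred consensus/ --ref expert_masks/ --out report.csv
crowdseg run       --config config.yaml --simulate sim.yaml --out run/
```

`crowdseg run` drives a whole simulated campaign and writes consensus masks,
`consensus.csv`, `difficulty.csv`, `profiles.csv`, `ledger.json` and a run
log. A config YAML mirrors `crowdseg.CampaignConfig`; write one with
`cs.default_config().to_yaml("config.yaml")`.

Masks are single-channel 8-bit PNGs (0 = background, 255 = foreground;
read threshold 128). Manifests are UTF-8 CSVs with columns
`annotator_id,frame_id,structure,role,mask_path,elapsed_s`
(role ∈ ordinary/training_gold/running_gold); expert references use
`frame_id,structure,expert_id,mask_path`. Paths are relative to the CSV.

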
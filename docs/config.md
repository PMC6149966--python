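# Pipeline configuration (`qamskit run`)

YAML file consumed by `qamskit run` / `qamskit.pipeline.run_pipeline`.

```yaml
output_dir: out/run1        # required; created if absent
seed: 42                    # single global seed; per-stage substreams are
                            # derived from it (default 0)
simulation:
  n_per_group: 6            # batches per quality group (default 6)
  noise_cv: 0.004           # proportional area noise (default 0.004)
  batch_cv: 0.10            # between-batch content CV (default 0.10)
extraction:
  powder_mass: 1.0          # g (default 1.0)
  extract_volume: 25.0      # mL (default 25.0)
```

Stages run in order: simulate calibration series → simulate batches →
fit curves and RCFs → quantify (QAMS and ESM) → cosine comparison →
clustering → discriminant analysis with leave-one-out validation. Each
stage logs one line (`-v`) with the output file and its SHA-256 prefix, and
every artifact listed in `docs/formats.md` is written to `output_dir`
alongside `summary.json` (cosines, RCFs, variance shares, LOO accuracy).

A failing stage raises before later stages run; artifacts already written
are retained. Identical configs (including `seed`) produce byte-identical
artifacts.
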
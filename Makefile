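.PHONY: test acceptance reproduce

test:
	python -m pytest -q tests/

acceptance:
	python scripts/acceptance.py --seed 1 --out results/acceptance.json

# Reproduction on the deposited processed dataset. Requires the study's
# supplementary files, downloaded by the user (see README "Reproducing the
# results"): a concentration matrix (CONC) and optionally a cluster
# assignment (CLUSTERS).
CONC ?= data/concentrations.tsv
CLUSTERS ?=
reproduce:
	python scripts/reproduce.py --concentrations $(CONC) \
		$(if $(CLUSTERS),--clusters $(CLUSTERS)) --consensus \
		--out results/reproduce.json
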
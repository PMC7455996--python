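.PHONY: install test demo acceptance

install:
	pip install --no-build-isolation -e .

test:
	python -m pytest -q

demo:
	python scripts/demo.py --seed 1 --out results/demo_metrics.tsv

acceptance:
	python scripts/acceptance.py --seed 1 --out results/acceptance.json
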
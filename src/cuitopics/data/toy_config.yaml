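# Example run config for the bundled toy fixture.
# Paths are resolved relative to the working directory; copy the bundled
# toy_posts.jsonl and toy_dictionary.tsv next to this file first, e.g.
#   python -c "from importlib import resources; import shutil;
#              d = resources.files('cuitopics.data');
#              [shutil.copy(d / f, f) for f in
#               ('toy_posts.jsonl', 'toy_dictionary.tsv', 'toy_config.yaml')]"
#   cuitopics run-all --config toy_config.yaml
posts: toy_posts.jsonl
dictionary: toy_dictionary.tsv
out_dir: toy_out
K_grid: [2]
alpha_grid: [1.5]
chosen_K: 2
chosen_alpha: 1.5
seed: 7
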
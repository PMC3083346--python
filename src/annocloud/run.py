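"""Run configuration, validation and the read->score->cluster->write pipeline.

This is the engine behind the command-line interface, exposed as a library
entry point so scripted runs get the same validation and logging.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

from . import cloud_core, cooccurrence, io_formats, text_pipeline
from .errors import ConfigError

log = logging.getLogger("annocloud")

LAYOUTS = ("simple", "clustered", "network")


@dataclass
class RunConfig:
    """Everything one run needs; precedence CLI flags > config file > defaults."""

    network_path: str | None = None
    attribute_table_path: str | None = None
    selection: list[str] | str = "all"  # ids, a file path, or "all"
    attributes: list[str] = field(default_factory=lambda: ["name"])
    k: float = 0.0
    threshold: float = cooccurrence.DEFAULT_THRESHOLD
    layout: str = "simple"
    min_font: int = cloud_core.DEFAULT_MIN_FONT
    max_font: int = cloud_core.DEFAULT_MAX_FONT
    out_path: str = "cloud.json"
    out_format: str | None = None
    delimiters: str | None = None
    stopwords_path: str | None = None
    drop_numbers: bool = True
    use_stemming: bool = True
    count_mode: str = "presence"
    pair_prob: str = "node"
    list_sep: str = "|"
    fixture_seed: int | None = None  # use the bundled fixture instead of files

    @classmethod
    def from_mappings(cls, *mappings: dict) -> "RunConfig":
        """Merge configuration dicts, later mappings taking precedence."""
        known = {f.name for f in fields(cls)}
        merged: dict = {}
        for m in mappings:
            for key, value in m.items():
                if key not in known:
                    raise ConfigError([f"unknown config key: {key!r}"])
                if value is not None:
                    merged[key] = value
        return cls(**merged)


def validate(config: RunConfig) -> list[str]:
    """Static validation; returns every violation (empty list iff runnable)."""
    v: list[str] = []
    if config.layout not in LAYOUTS:
        v.append(f"layout: must be one of {'/'.join(LAYOUTS)}, got {config.layout!r}")
    if not 0.0 <= config.k <= 1.0:
        v.append(f"k: must lie in [0, 1], got {config.k}")
    if config.threshold <= 0:
        v.append(f"threshold: must be > 0, got {config.threshold}")
    if config.min_font <= 0 or config.max_font <= 0 or config.min_font > config.max_font:
        v.append(f"font range: invalid [{config.min_font}, {config.max_font}]")
    if config.count_mode not in ("presence", "occurrence"):
        v.append(f"count_mode: must be presence|occurrence, got {config.count_mode!r}")
    if config.pair_prob not in ("node", "position"):
        v.append(f"pair_prob: must be node|position, got {config.pair_prob!r}")
    if config.fixture_seed is None:
        if not config.network_path:
            v.append("network_path: required unless running on the fixture")
        elif not Path(config.network_path).exists():
            v.append(f"network_path: no such file {config.network_path!r}")
        if config.attribute_table_path and not Path(config.attribute_table_path).exists():
            v.append(
                f"attribute_table_path: no such file {config.attribute_table_path!r}"
            )
    if not config.attributes:
        v.append("attributes: at least one attribute name is required")
    if isinstance(config.selection, str) and config.selection != "all":
        if not Path(config.selection).exists():
            v.append(f"selection: no such file {config.selection!r}")
    return v


def _load_inputs(config: RunConfig):
    if config.fixture_seed is not None:
        net, fixture_sel = io_formats.generate_fixture(config.fixture_seed)
    else:
        net = io_formats.read_network(config.network_path)
        fixture_sel = None
        if config.attribute_table_path:
            table = io_formats.read_attributes(
                config.attribute_table_path, config.list_sep
            )
            io_formats.attach_attributes(net, table)
    if config.selection == "all":
        # on the fixture, "all" means the dense cluster the fixture selects
        selection = set(net.nodes) if fixture_sel is None else set(fixture_sel)
    elif isinstance(config.selection, str):
        selection = {
            line.strip()
            for line in Path(config.selection).read_text().splitlines()
            if line.strip()
        }
    else:
        selection = set(config.selection)
    return net, selection


def _data_violations(config: RunConfig, net, selection) -> list[str]:
    v = []
    unknown = sorted(selection - net.nodes)
    if unknown:
        v.append(f"selection: node(s) not in network: {', '.join(unknown)}")
    present = {name for attrs in net.attributes.values() for name in attrs}
    for name in config.attributes:
        if name not in present:
            v.append(f"attributes: {name!r} not present on any node")
    return v


def run(config: RunConfig) -> int:
    """Execute one run; writes the requested layout and returns 0 on success.

    Raises :class:`ConfigError` listing every violation when the
    configuration is not runnable.
    """
    violations = validate(config)
    if violations:
        raise ConfigError(violations)
    net, selection = _load_inputs(config)
    violations = _data_violations(config, net, selection)
    if violations:
        raise ConfigError(violations)

    text_cfg = text_pipeline.TextConfig(
        delimiters=(
            frozenset(config.delimiters)
            if config.delimiters
            else text_pipeline.DEFAULT_DELIMITERS
        ),
        stopwords=(
            text_pipeline.load_stopwords(config.stopwords_path)
            if config.stopwords_path
            else text_pipeline.default_stopwords()
        ),
        drop_numbers=config.drop_numbers,
        use_stemming=config.use_stemming,
    )
    corpus = text_pipeline.build_corpus(net.documents(config.attributes), text_cfg)
    log.info(
        "effective parameters: layout=%s k=%g threshold=%g fonts=[%d, %d] "
        "count_mode=%s pair_prob=%s stemming=%s",
        config.layout, config.k, config.threshold, config.min_font,
        config.max_font, config.count_mode, config.pair_prob,
        config.use_stemming,
    )
    log.info(
        "network: %d nodes, %d edges; selection: %d nodes",
        len(net.nodes), len(net.edges), len(selection),
    )

    out = Path(config.out_path)
    if config.layout == "simple":
        cloud = cloud_core.build_simple_cloud(
            corpus, selection, config.k, config.min_font, config.max_font,
            config.count_mode,
        )
        log.info("simple cloud: %d words", len(cloud))
        io_formats.write_cloud(cloud, out, config.out_format)
    elif config.layout == "clustered":
        clustered = cooccurrence.build_clustered_cloud(
            corpus, selection, config.k, config.threshold, config.min_font,
            config.max_font, config.count_mode, config.pair_prob,
        )
        n_words = sum(len(c.words) for c in clustered.clusters)
        log.info(
            "clustered cloud: %d words in %d clusters (threshold %g)",
            n_words, len(clustered.clusters), config.threshold,
        )
        io_formats.write_cloud(clustered, out, config.out_format)
    else:  # network
        cloud = cloud_core.build_simple_cloud(
            corpus, selection, config.k, config.min_font, config.max_font,
            config.count_mode,
        )
        stats = cloud_core.count_words(corpus, selection, "presence")
        pairs = cooccurrence.pair_scores(corpus, selection, stats, config.pair_prob)
        g = cooccurrence.build_word_network(pairs, cloud.stems(), cloud.fonts())
        log.info(
            "word network: %d words, %d edges",
            g.number_of_nodes(), g.number_of_edges(),
        )
        io_formats.write_word_network(g, out, config.out_format)
    log.info("wrote %s", out)
    return 0
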
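{
  "description": "Network-characteristics table plus provenance.\n\n``mean_shortest_path_rand_diff`` is recomputed from the report's own\nunrounded path fields; ``is_small_world`` is (sigma > 1) and\n``is_assortative`` is (assortativity > 0).",
  "properties": {
    "network_type": {
      "default": "Undirected",
      "title": "Network Type",
      "type": "string"
    },
    "adjacency_matrix": {
      "default": "Symmetric",
      "title": "Adjacency Matrix",
      "type": "string"
    },
    "n_nodes": {
      "minimum": 0,
      "title": "N Nodes",
      "type": "integer"
    },
    "n_edges_unordered": {
      "minimum": 0,
      "title": "N Edges Unordered",
      "type": "integer"
    },
    "n_edges_ordered": {
      "minimum": 0,
      "title": "N Edges Ordered",
      "type": "integer"
    },
    "n_random_networks": {
      "minimum": 1,
      "title": "N Random Networks",
      "type": "integer"
    },
    "graph_density": {
      "maximum": 1.0,
      "minimum": 0.0,
      "title": "Graph Density",
      "type": "number"
    },
    "diameter": {
      "minimum": 0,
      "title": "Diameter",
      "type": "integer"
    },
    "global_clustering_coefficient": {
      "maximum": 1.0,
      "minimum": 0.0,
      "title": "Global Clustering Coefficient",
      "type": "number"
    },
    "average_local_clustering": {
      "maximum": 1.0,
      "minimum": 0.0,
      "title": "Average Local Clustering",
      "type": "number"
    },
    "mean_shortest_path": {
      "exclusiveMinimum": 0.0,
      "title": "Mean Shortest Path",
      "type": "number"
    },
    "mean_shortest_path_rand": {
      "exclusiveMinimum": 0.0,
      "title": "Mean Shortest Path Rand",
      "type": "number"
    },
    "mean_shortest_path_rand_diff": {
      "title": "Mean Shortest Path Rand Diff",
      "type": "number"
    },
    "assortativity": {
      "maximum": 1.0,
      "minimum": -1.0,
      "title": "Assortativity",
      "type": "number"
    },
    "modularity": {
      "maximum": 1.0,
      "minimum": -1.0,
      "title": "Modularity",
      "type": "number"
    },
    "n_communities": {
      "minimum": 1,
      "title": "N Communities",
      "type": "integer"
    },
    "gamma": {
      "exclusiveMinimum": 0.0,
      "title": "Gamma",
      "type": "number"
    },
    "lam": {
      "exclusiveMinimum": 0.0,
      "title": "Lam",
      "type": "number"
    },
    "sigma": {
      "exclusiveMinimum": 0.0,
      "title": "Sigma",
      "type": "number"
    },
    "is_small_world": {
      "title": "Is Small World",
      "type": "boolean"
    },
    "is_assortative": {
      "title": "Is Assortative",
      "type": "boolean"
    },
    "graph_file": {
      "anyOf": [
        {
          "type": "string"
        },
        {
          "type": "null"
        }
      ],
      "title": "Graph File"
    },
    "roster_file": {
      "anyOf": [
        {
          "type": "string"
        },
        {
          "type": "null"
        }
      ],
      "title": "Roster File"
    },
    "seed": {
      "title": "Seed",
      "type": "integer"
    },
    "t_steps": {
      "title": "T Steps",
      "type": "integer"
    },
    "config": {
      "additionalProperties": true,
      "title": "Config",
      "type": "object"
    },
    "version": {
      "title": "Version",
      "type": "string"
    },
    "timestamp": {
      "title": "Timestamp",
      "type": "number"
    }
  },
  "required": [
    "n_nodes",
    "n_edges_unordered",
    "n_edges_ordered",
    "n_random_networks",
    "graph_density",
    "diameter",
    "global_clustering_coefficient",
    "average_local_clustering",
    "mean_shortest_path",
    "mean_shortest_path_rand",
    "mean_shortest_path_rand_diff",
    "assortativity",
    "modularity",
    "n_communities",
    "gamma",
    "lam",
    "sigma",
    "is_small_world",
    "is_assortative",
    "graph_file",
    "roster_file",
    "seed",
    "t_steps",
    "config",
    "version",
    "timestamp"
  ],
  "title": "AnalysisReport",
  "type": "object"
}
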
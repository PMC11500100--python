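<?xml version='1.0' encoding='utf-8'?>
<simulation>
  <domain x_min="-200.0" x_max="200.0" y_min="-200.0" y_max="200.0" voxel_size="20.0" />
  <overall dt_mechanics="0.1" dt_diffusion="0.05" t_max="960.0" output_interval="120.0" />
  <options rng_seed="0" adjacency_rings="2" />
  <substrate diffusion_coefficient="800.0" decay_rate="0.02" />
  <cell_definitions>
    <cell_definition name="wall_fibre" initial_count="0">
      <custom_data>
        <fibre_length>40.0</fibre_length>
        <length_normdist_sd>0.0</length_normdist_sd>
        <fibre_radius>2.0</fibre_radius>
        <radius_normdist_sd>0.0</radius_normdist_sd>
        <anisotropic_fibres>1</anisotropic_fibres>
        <fibre_angle>1.5707963267948966</fibre_angle>
        <angle_normdist_sd>0.0</angle_normdist_sd>
        <fibre_sticky>1.0</fibre_sticky>
      </custom_data>
      <initial_positions>
        <position x="0.0" y="-180.0" />
        <position x="0.0" y="-140.0" />
        <position x="0.0" y="-100.0" />
        <position x="0.0" y="-60.0" />
        <position x="0.0" y="-20.0" />
        <position x="0.0" y="20.0" />
        <position x="0.0" y="60.0" />
        <position x="0.0" y="100.0" />
        <position x="0.0" y="140.0" />
        <position x="0.0" y="180.0" />
      </initial_positions>
    </cell_definition>
    <cell_definition name="ecm_field" initial_count="60">
      <custom_data>
        <fibre_length>40.0</fibre_length>
        <length_normdist_sd>0.0</length_normdist_sd>
        <fibre_radius>2.0</fibre_radius>
        <radius_normdist_sd>0.0</radius_normdist_sd>
        <anisotropic_fibres>0</anisotropic_fibres>
        <fibre_angle>0.0</fibre_angle>
        <angle_normdist_sd>0.0</angle_normdist_sd>
        <fibre_sticky>1.0</fibre_sticky>
      </custom_data>
    </cell_definition>
    <cell_definition name="chemotactic_cell" initial_count="0">
      <phenotype radius="10.0" migration_speed="1.0" chemotactic="1" secretion_rate="0.0" cell_cell_repulsion="10.0" cell_cell_adhesion="0.4" adhesion_scale="1.25" />
      <custom_data>
        <vel_adhesion>0.1</vel_adhesion>
        <vel_contact>0.2</vel_contact>
        <cell_velocity_max>10.0</cell_velocity_max>
        <s_exponent>1.0</s_exponent>
        <r_exponent>2.0</r_exponent>
        <fibre_pushing>0</fibre_pushing>
        <fibre_rotation>0</fibre_rotation>
        <fibre_degradation>1</fibre_degradation>
        <fibre_custom_degradation>0</fibre_custom_degradation>
        <fibre_stuck_time>30</fibre_stuck_time>
        <fibre_stuck_threshold>0.5</fibre_stuck_threshold>
        <fibre_pressure_threshold>0.25</fibre_pressure_threshold>
        <fibre_degradation_rate>1.0</fibre_degradation_rate>
        <color_cells_by_pressure>0</color_cells_by_pressure>
      </custom_data>
      <initial_positions>
        <position x="-150.0" y="0.0" />
      </initial_positions>
    </cell_definition>
    <cell_definition name="source_cell" initial_count="0">
      <phenotype radius="10.0" migration_speed="0.0" chemotactic="0" secretion_rate="10.0" cell_cell_repulsion="10.0" cell_cell_adhesion="0.4" adhesion_scale="1.25" />
      <custom_data>
        <vel_adhesion>0.0</vel_adhesion>
        <vel_contact>0.0</vel_contact>
        <cell_velocity_max>10.0</cell_velocity_max>
        <s_exponent>1.0</s_exponent>
        <r_exponent>2.0</r_exponent>
        <fibre_pushing>0</fibre_pushing>
        <fibre_rotation>0</fibre_rotation>
        <fibre_degradation>0</fibre_degradation>
        <fibre_custom_degradation>0</fibre_custom_degradation>
        <fibre_stuck_time>50</fibre_stuck_time>
        <fibre_stuck_threshold>0.5</fibre_stuck_threshold>
        <fibre_pressure_threshold>0.25</fibre_pressure_threshold>
        <fibre_degradation_rate>1.0</fibre_degradation_rate>
        <color_cells_by_pressure>0</color_cells_by_pressure>
      </custom_data>
      <initial_positions>
        <position x="150.0" y="0.0" />
      </initial_positions>
    </cell_definition>
  </cell_definitions>
</simulation>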
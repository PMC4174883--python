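<Lems>
    <!-- Network composition: a population expands into independent cell
         instances via MultiInstantiate; a synapticConnection wires one
         cell's spike port to another cell, instantiating its referenced
         synapse component onto the target's attachment slot with the given
         delay and weight. -->

    <Include file="defs.xml"/>
    <Include file="basetypes.xml"/>

    <ComponentType name="population">
        <Parameter name="size" dimension="none"/>
        <ComponentReference name="component" type="baseCell"/>
        <Structure>
            <MultiInstantiate number="size" component="component"/>
        </Structure>
    </ComponentType>

    <ComponentType name="synapticConnection">
        <Text name="from"/>
        <Text name="to"/>
        <Parameter name="delay" dimension="time"/>
        <Parameter name="weight" dimension="none"/>
        <ComponentReference name="synapse" type="baseSynapse"/>
        <Structure>
            <EventConnection from="from" to="to" sourcePort="spike" targetPort="in"
                             delay="delay" weight="weight"
                             receiver="synapse" receiverContainer="synapses"/>
        </Structure>
    </ComponentType>

    <ComponentType name="network">
        <Children name="populations" type="population"/>
        <Children name="connections" type="synapticConnection"/>
    </ComponentType>
</Lems>
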
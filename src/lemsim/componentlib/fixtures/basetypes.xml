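<Lems>
    <!-- Base type hierarchy shared by the cell, synapse and network
         fixtures: anything producing a current, event sources, spiking
         cells with a membrane potential, and the base synapse that
         receives events and produces a current. -->

    <Include file="defs.xml"/>

    <ComponentType name="basePointCurrent">
        <Exposure name="i" dimension="current"/>
    </ComponentType>

    <!-- Square current pulse: amplitude between delay and delay+duration.
         Realized with an event-assigned state variable so no piecewise
         expressions are needed. -->
    <ComponentType name="pulseGenerator" extends="basePointCurrent">
        <Parameter name="delay" dimension="time"/>
        <Parameter name="duration" dimension="time"/>
        <Parameter name="amplitude" dimension="current"/>
        <Dynamics>
            <StateVariable name="i" dimension="current" exposure="i"/>
            <OnCondition test="t .geq. delay .and. t .lt. delay + duration">
                <StateAssignment variable="i" value="amplitude"/>
            </OnCondition>
            <OnCondition test="t .geq. delay + duration">
                <StateAssignment variable="i" value="0 * amplitude"/>
            </OnCondition>
        </Dynamics>
    </ComponentType>

    <ComponentType name="baseSpikeSource">
        <EventPort name="spike" direction="out"/>
    </ComponentType>

    <!-- Regular spike train on [start, stop) with the given period. -->
    <ComponentType name="spikeGenerator" extends="baseSpikeSource">
        <Parameter name="period" dimension="time"/>
        <Parameter name="start" dimension="time"/>
        <Parameter name="stop" dimension="time"/>
        <Dynamics>
            <StateVariable name="tnext" dimension="time"/>
            <OnStart>
                <StateAssignment variable="tnext" value="start"/>
            </OnStart>
            <OnCondition test="t .geq. tnext .and. t .lt. stop">
                <EventOut port="spike"/>
                <StateAssignment variable="tnext" value="tnext + period"/>
            </OnCondition>
        </Dynamics>
    </ComponentType>

    <ComponentType name="baseCell"/>

    <ComponentType name="baseSpikingCell" extends="baseCell">
        <EventPort name="spike" direction="out"/>
    </ComponentType>

    <ComponentType name="baseCellMembPot" extends="baseSpikingCell">
        <Exposure name="v" dimension="voltage"/>
    </ComponentType>

    <ComponentType name="baseSynapse" extends="basePointCurrent">
        <EventPort name="in" direction="in"/>
    </ComponentType>
</Lems>
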